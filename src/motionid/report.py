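"""Tables, figures and manifests summarizing experiment results.

Results from :func:`motionid.experiments.run_experiment` are aggregated per
configuration (experiment family, model, training length, gap, train/test
type) across targets with median/IQR, then written as deterministic CSV
tables, line/box plots, and a JSON manifest linking every file to the specs
and seeds that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .experiments import ExperimentResult
from .metrics import METRIC_NAMES, summarize

__all__ = ["render_reports", "results_to_json", "results_from_json", "summary_table"]


def _family(rq_id: str) -> str:
    if rq_id in ("rq2_forward", "rq3_backward"):
        return "rq2_rq3"
    if rq_id.startswith("rq4"):
        return "rq4"
    return rq_id


def _group_key(result: ExperimentResult) -> tuple:
    meta = result.spec.meta
    return (
        result.spec.rq_id,
        result.model_kind,
        meta.get("train_minutes"),
        result.spec.gap_to_test_min,
        meta.get("train_kind"),
        meta.get("test_kind"),
        meta.get("offset"),
    )


def summary_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """One row per configuration: median and quartiles per metric over targets."""
    if not results:
        raise ValueError("no results to summarize")
    groups: dict[tuple, list[ExperimentResult]] = {}
    for r in results:
        groups.setdefault(_group_key(r), []).append(r)
    rows = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        rq, model, minutes, gap, train_kind, test_kind, offset = key
        members = groups[key]
        summ = summarize([m.metrics for m in members])
        row = {
            "rq": rq,
            "model": model,
            "train_minutes": minutes,
            "gap_to_test_min": gap,
            "train_kind": train_kind,
            "test_kind": test_kind,
            "offset": offset,
            "n_targets": summ.n_targets,
        }
        for name in METRIC_NAMES:
            row[f"{name}_median"] = summ.median[name]
            row[f"{name}_q25"] = summ.q25[name]
            row[f"{name}_q75"] = summ.q75[name]
        rows.append(row)
    return pd.DataFrame(rows)


def _plot_sweep(table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for rq, label in (
        ("rq2_forward", "growing from timeline start"),
        ("rq3_backward", "trimmed, adjacent to test"),
    ):
        sub = table[table["rq"] == rq].sort_values("train_minutes")
        if sub.empty:
            continue
        ax.plot(sub["train_minutes"], sub["f1_median"], marker="o", label=label)
        ax.fill_between(sub["train_minutes"], sub["f1_q25"], sub["f1_q75"], alpha=0.2)
    ax.set_xlabel("training minutes")
    ax.set_ylabel("F1 (median, IQR)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_rq1_box(results: list[ExperimentResult], path: Path) -> None:
    models = sorted({r.model_kind for r in results})
    fig, axes = plt.subplots(1, len(METRIC_NAMES), figsize=(12, 3.5), sharey=True)
    for ax, metric in zip(axes, METRIC_NAMES):
        data = [
            [getattr(r.metrics, metric) for r in results if r.model_kind == m]
            for m in models
        ]
        ax.boxplot(data, tick_labels=models)
        ax.set_title(metric)
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_rq4(table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (train_kind, test_kind), sub in table.groupby(["train_kind", "test_kind"]):
        sub = sub.sort_values("offset")
        ax.plot(
            sub["offset"],
            sub["f1_median"],
            marker="o",
            label=f"train {train_kind} / test {test_kind}",
        )
    ax.set_xlabel("sliding training-block offset")
    ax.set_ylabel("F1 (median)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_reports(results: list[ExperimentResult], out_dir) -> list[Path]:
    """Write per-family CSV tables, plots and a JSON manifest; returns paths."""
    if not results:
        raise ValueError("no results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = summary_table(results)
    written: list[Path] = []
    manifest: dict = {"files": {}, "results": []}
    for r in results:
        manifest["results"].append(
            {
                "rq_id": r.spec.rq_id,
                "model_kind": r.model_kind,
                "target": r.spec.target_user_id,
                "seed": r.spec.seed,
                "meta": dict(r.spec.meta),
            }
        )
    for family in sorted({_family(rq) for rq in table["rq"]}):
        sub = table[[_family(rq) == family for rq in table["rq"]]]
        csv_path = out_dir / f"{family}_summary.csv"
        sub.to_csv(csv_path, index=False)
        written.append(csv_path)
        manifest["files"][csv_path.name] = {"kind": "table", "family": family}
        plot_path = out_dir / f"{family}_f1.png"
        if family == "rq1":
            _plot_rq1_box([r for r in results if r.spec.rq_id == "rq1"], plot_path)
        elif family == "rq2_rq3":
            _plot_sweep(sub, plot_path)
        else:
            _plot_rq4(sub, plot_path)
        written.append(plot_path)
        manifest["files"][plot_path.name] = {"kind": "figure", "family": family}
    manifest_path = out_dir / "report_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written


def results_to_json(results: list[ExperimentResult], path) -> None:
    """Serialize results deterministically (sorted keys, plain types)."""
    payload = [r.to_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def results_from_json(path) -> list[ExperimentResult]:
    """Rehydrate serialized results (enough for re-rendering reports)."""
    from .experiments import ExperimentSpec, Selection
    from .metrics import MetricsSet

    payload = json.loads(Path(path).read_text())
    results = []
    for item in payload:
        s = item["spec"]
        spec = ExperimentSpec(
            rq_id=s["rq_id"],
            target_user_id=s["target_user_id"],
            decoy_user_ids=tuple(s["decoy_user_ids"]),
            train_selection=tuple(
                Selection(user_id=d["user_id"], minutes=tuple(d["minutes"]))
                for d in s["train_selection"]
            ),
            test_selection=tuple(
                Selection(user_id=d["user_id"], minutes=tuple(d["minutes"]))
                for d in s["test_selection"]
            ),
            seed=s["seed"],
            gap_to_test_min=s["gap_to_test_min"],
            meta=s["meta"],
        )
        preds = pd.DataFrame(item["predictions"])
        results.append(
            ExperimentResult(
                spec=spec,
                model_kind=item["model_kind"],
                metrics=MetricsSet(**item["metrics"]),
                predictions=preds,
                chosen_hyperparameters=item["chosen_hyperparameters"],
                n_train=item["n_train"],
                n_test=item["n_test"],
            )
        )
    return results
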
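"""End-to-end orchestration: cohort on disk -> connectomes -> metrics ->
state taxonomy -> clinical delta correlations -> summary.

The stages mirror the analysis a three-condition connectivity study runs:
build each session's weighted and binarised connectome, summarise group
sparsity with frequency matrices, compute node metrics, assign every edge
and every (node, metric) a disorder/cured/activated/unchanged state, and
correlate the per-patient changes of the non-unchanged features with the
clinical score changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as clf
from . import cohort as coh
from . import metrics as gm
from . import network as net
from . import stats as st

__all__ = ["AnalysisParams", "run_simulate", "run_analyze", "run_classify"]

log = logging.getLogger("fcstates")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class AnalysisParams:
    alpha: float = 0.05
    correction: str = "bonferroni"  # bonferroni | none
    t_variant: str = "welch"  # welch | pooled
    efficiency_mode: str = "literal"  # literal | neighborhood

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.t_variant not in ("welch", "pooled"):
            raise ValueError(f"unknown t variant {self.t_variant!r}")
        if self.efficiency_mode not in ("literal", "neighborhood"):
            raise ValueError(f"unknown efficiency mode {self.efficiency_mode!r}")


def run_simulate(config: coh.SynthConfig, outdir: str | Path) -> coh.CohortBundle:
    """Generate a synthetic cohort bundle on disk."""
    bundle = coh.generate_cohort(config, outdir)
    log.info("simulated cohort: %d controls, %d patients x 2 sessions, "
             "R=%d, T=%d, seed=%d", config.n_controls, config.n_patients,
             config.n_rois, config.n_timepoints, config.seed)
    return bundle


def _connectomes(bundle: coh.CohortBundle) -> list[net.WeightedConnectome]:
    out = []
    for s in bundle.sessions:
        r = net.compute_fc(s)
        out.append(net.fisher_z(r, s.roi_labels, subject_id=s.subject_id,
                                group=s.group, session=s.session))
    return out


def _design_from_bundle(bundle: coh.CohortBundle) -> st.StudyDesign:
    d = bundle.design
    controls = d.loc[d["group"] == "NC", "subject_id"].tolist()
    patients = d.loc[d["session"] == "baseline", "subject_id"].tolist()
    post = set(d.loc[d["session"] == "post", "subject_id"])
    unpaired = [p for p in patients if p not in post]
    if unpaired:
        raise ValueError(f"patients without a post session: {unpaired}")
    return st.StudyDesign(controls=controls, patients=patients)


def _weight_stack(connectomes: Sequence[net.WeightedConnectome],
                  subject_order: Sequence[str], session: str,
                  iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    by_key = {(c.subject_id, c.session): c for c in connectomes}
    rows = []
    for sid in subject_order:
        c = by_key.get((sid, session))
        if c is None:
            raise KeyError(f"missing connectome for ({sid}, {session})")
        rows.append(c.z_weights[iu])
    return np.asarray(rows)


def run_analyze(cohort_dir: str | Path, outdir: str | Path,
                params: AnalysisParams | None = None) -> dict:
    """Run every analysis stage on a cohort directory; return the summary."""
    params = params or AnalysisParams()
    params.validate()
    cohort_dir = Path(cohort_dir)
    for required in ("design.csv", "clinical.csv"):
        if not (cohort_dir / required).exists():
            raise FileNotFoundError(f"missing input file: {cohort_dir / required}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = coh.load_cohort(cohort_dir)
    design = _design_from_bundle(bundle)
    labels = bundle.sessions[0].roi_labels
    r = len(labels)
    log.info("analyze: %d sessions, R=%d", len(bundle.sessions), r)

    connectomes = _connectomes(bundle)
    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for c in connectomes:
        np.savetxt(conn_dir / f"{c.subject_id}_{c.session}.tsv", c.z_weights,
                   fmt="%.10g", delimiter="\t",
                   header="\t".join(c.roi_labels), comments="")

    binaries = [net.binarize_positive(c) for c in connectomes]
    sparsity = {}
    for cond, sess in (("NC", "single"), ("IBSbs", "baseline"), ("IBS1st", "post")):
        nets = [b for b in binaries if b.session == sess]
        freq = net.frequency_matrix(nets)
        np.savetxt(out / f"frequency_{cond}.tsv", freq.counts, fmt="%d",
                   delimiter="\t", header="\t".join(labels), comments="")
        sparsity[cond] = {"n_subjects": freq.n_subjects,
                          "unconnected_edges": net.count_unconnected_edges(freq)}

    metric_table = gm.node_metric_table(binaries, mode=params.efficiency_mode)
    metric_table.to_csv(out / "node_metrics.csv", index=False, float_format="%.10g")

    iu = np.triu_indices(r, k=1)
    edges = [(labels[i], labels[j]) for i, j in zip(*iu)]
    nc_w = _weight_stack(connectomes, design.controls, "single", iu)
    bs_w = _weight_stack(connectomes, design.patients, "baseline", iu)
    post_w = _weight_stack(connectomes, design.patients, "post", iu)
    edge_records = st.classify_edge_states(
        nc_w, bs_w, post_w, edges, alpha=params.alpha,
        correction=params.correction, variant=params.t_variant)
    _records_to_csv(edge_records, out / "edge_states.csv",
                    key_cols=("roi_i", "roi_j"))

    node_records = st.classify_node_metric_states(
        metric_table, design, alpha=params.alpha,
        correction=params.correction, variant=params.t_variant)
    _records_to_csv(node_records, out / "node_metric_states.csv",
                    key_cols=("roi", "metric"))

    feature_deltas: dict[tuple, np.ndarray] = {}
    for rec, k in zip(edge_records, range(len(edges))):
        if rec.state != "unchanged":
            feature_deltas[rec.feature] = post_w[:, k] - bs_w[:, k]
    for metric in ("degree", "clustering", "local_efficiency"):
        piv_b = metric_table[metric_table["session"] == "baseline"].pivot(
            index="subject_id", columns="roi", values=metric)
        piv_p = metric_table[metric_table["session"] == "post"].pivot(
            index="subject_id", columns="roi", values=metric)
        for rec in node_records:
            roi, m = rec.feature
            if m == metric and rec.state != "unchanged":
                feature_deltas[rec.feature] = (
                    piv_p.loc[design.patients, roi].to_numpy(float)
                    - piv_b.loc[design.patients, roi].to_numpy(float))
    correlations = st.delta_correlations(feature_deltas, bundle.clinical, design)
    corr_frame = pd.DataFrame(
        [{"feature_i": c.feature[0], "feature_j": c.feature[1],
          "score": c.score, "r": c.r, "p": c.p, "n": c.n}
         for c in correlations],
        columns=["feature_i", "feature_j", "score", "r", "p", "n"])
    corr_frame.to_csv(out / "delta_correlations.csv", index=False,
                      float_format="%.10g")

    state_counts = {s: 0 for s in st.STATES}
    for rec in edge_records:
        state_counts[rec.state] += 1
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_sessions": len(bundle.sessions),
        "n_rois": r,
        "params": asdict(params),
        "sparsity": sparsity,
        "edge_state_counts": state_counts,
        "node_metric_nonunchanged": sum(rec.state != "unchanged"
                                        for rec in node_records),
        "delta_correlations": [
            {"feature": list(c.feature), "score": c.score,
             "r": c.r, "p": c.p, "n": c.n} for c in correlations],
        "outputs": sorted(str(p.relative_to(out))
                          for p in out.rglob("*") if p.is_file()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("analyze done: edge states %s", state_counts)
    return summary


def _records_to_csv(records: Sequence[st.EdgeStateRecord], path: Path,
                    key_cols: tuple[str, str]) -> None:
    rows = []
    for rec in records:
        rows.append({
            key_cols[0]: rec.feature[0], key_cols[1]: rec.feature[1],
            "t1": rec.nc_vs_bs.statistic, "p1": rec.nc_vs_bs.p,
            "p1_corr": rec.nc_vs_bs.p_corrected,
            "t2": rec.bs_vs_1st.statistic, "p2": rec.bs_vs_1st.p,
            "p2_corr": rec.bs_vs_1st.p_corrected,
            "t3": rec.nc_vs_1st.statistic, "p3": rec.nc_vs_1st.p,
            "p3_corr": rec.nc_vs_1st.p_corrected,
            "F": rec.anova.statistic, "pF": rec.anova.p,
            "state": rec.state, "direction": rec.direction,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def run_classify(train_dir: str | Path, test_dir: str | Path,
                 edges: Sequence[tuple[str, str]], comparison: tuple[str, str],
                 outdir: str | Path,
                 svm: clf.SvmConfig | None = None) -> clf.ClassificationReport:
    """Train on one cohort's connectomes, validate on a held-out cohort.

    ``comparison`` names the two conditions to discriminate, e.g.
    ("NC", "IBSbs"); sessions of other conditions are ignored.
    """
    svm = svm or clf.SvmConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for d in (train_dir, test_dir):
        bundle = coh.load_cohort(d)
        conns = [c for c in _connectomes(bundle) if c.group in comparison]
        if not conns:
            raise ValueError(f"no sessions of conditions {comparison} in {d}")
        tables.append(clf.extract_features(conns, edges, [c.group for c in conns]))
    report = clf.train_validate(tables[0], tables[1], svm,
                                comparison="-vs-".join(comparison))
    report.roc.to_csv(out / "roc.csv", index=False, float_format="%.10g")
    (out / "classification_report.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
    log.info("classify %s: accuracy=%.3f auc=%.3f", report.comparison,
             report.accuracy, report.auc)
    return report
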
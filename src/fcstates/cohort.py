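"""Synthetic three-condition cohort generator with known planted structure.

The generator emulates the study design the analysis pipeline expects:
normal controls (NC) scanned once, and a patient cohort scanned at
baseline (IBSbs) and again after a six-week intervention (IBS1st),
together with clinical scores (IBS-SSS symptom severity, IBS-QOL quality
of life, HAMA anxiety).

Time series are stationary zero-mean multivariate normal draws whose
population correlation matrix is a per-condition target built from a base
equicorrelation level plus planted edge effects:

* ``disorder`` — the edge differs from the control level at baseline and
  stays abnormal after treatment;
* ``cured`` — abnormal at baseline, back at the control level after;
* ``activated`` — at the control level at baseline, shifted away from
  both control and baseline levels after.

Targets are repaired to the nearest positive semi-definite correlation
matrix by eigenvalue clipping; if the repair moves a planted entry by
delta/10 or more the configuration is rejected rather than silently
distorted.  Clinical scores follow the per-condition normal parameters;
a patient's score *change* can be coupled (correlation rho) to the
realised Fisher-z weight change of a planted edge.

Everything is driven by a single integer seed expanded into independent
per-session substreams, so any subset of the cohort is reproducible.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import RoiTimeSeries, compute_fc

__all__ = [
    "CONDITIONS",
    "SCORES",
    "TABLE1_CLINICAL",
    "PlantedEdge",
    "SynthConfig",
    "SyntheticTruth",
    "CohortBundle",
    "aal116_labels",
    "build_group_targets",
    "simulate_timeseries",
    "simulate_clinical",
    "simulate_cohort",
    "generate_cohort",
    "load_cohort",
]

CONDITIONS = ("NC", "IBSbs", "IBS1st")
SCORES = ("ibs_sss", "ibs_qol", "hama")

# Published cohort clinical parameters: mean (SD) per condition.  Controls
# are assessed on the anxiety scale only.
TABLE1_CLINICAL: dict[str, dict[str, tuple[float, float]]] = {
    "NC": {"hama": (2.48, 2.9)},
    "IBSbs": {"ibs_sss": (245.5, 100.0), "ibs_qol": (132.46, 33.1),
              "hama": (15.25, 7.9)},
    "IBS1st": {"ibs_sss": (91.9, 49.0), "ibs_qol": (150.33, 13.6),
               "hama": (8.17, 2.9)},
}

_STATES = ("disorder", "cured", "activated")
_DIRECTIONS = ("increase", "decrease")
_PSD_FLOOR = 1e-6


def aal116_labels() -> list[str]:
    """The 116 region labels of the AAL cortical+cerebellar atlas."""
    text = (importlib.resources.files("fcstates") / "data" /
            "aal116_labels.txt").read_text()
    return text.split()


@dataclass(frozen=True)
class PlantedEdge:
    """One edge effect: state, direction and size of the planted shift.

    ``normal_level`` is the control-level correlation at this edge; it
    defaults to the base correlation.  ``direction`` says whether the
    abnormal condition sits ``delta`` above or below the normal level.
    """

    i: int
    j: int
    state: str
    direction: str = "increase"
    delta: float = 0.3
    normal_level: float | None = None

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.i >= self.j:
            raise ValueError("planted edge must have i < j")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class SynthConfig:
    n_controls: int = 23
    n_patients: int = 24
    n_rois: int = 116
    n_timepoints: int = 200  # 210 acquired volumes minus 10 discarded
    base_correlation: float | np.ndarray = 0.1
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    clinical_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: TABLE1_CLINICAL)
    delta_coupling: Mapping[tuple[tuple[int, int], str], float] = field(
        default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if np.isscalar(self.base_correlation):
            if not -1.0 < float(self.base_correlation) < 1.0:
                raise ValueError("base correlation must lie in (-1, 1)")
        else:
            b = np.asarray(self.base_correlation, float)
            if b.shape != (self.n_rois, self.n_rois):
                raise ValueError("base matrix shape mismatch")
            if not np.allclose(b, b.T) or not np.allclose(np.diag(b), 1.0):
                raise ValueError("base matrix must be symmetric with unit diagonal")
        seen: set[tuple[int, int]] = set()
        for e in self.planted_edges:
            if not (0 <= e.i < e.j < self.n_rois):
                raise ValueError(f"planted edge {e.key} outside 0..{self.n_rois - 1}")
            if e.key in seen:
                raise ValueError(f"duplicate planted edge {e.key}")
            seen.add(e.key)
        for (edge, score), rho in self.delta_coupling.items():
            if tuple(edge) not in seen:
                raise ValueError(f"coupling requested for unplanted edge {edge}")
            if score not in SCORES:
                raise ValueError(f"unknown clinical score {score!r}")
            if not 0.0 <= abs(rho) < 1.0:
                raise ValueError("|rho| must lie in [0, 1)")
        per_score: dict[str, int] = {}
        for (_, score) in self.delta_coupling:
            per_score[score] = per_score.get(score, 0) + 1
        multi = [s for s, c in per_score.items() if c > 1]
        if multi:
            raise ValueError(f"multiple edge couplings onto one score: {multi}")
        for cond, params in self.clinical_params.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            for score, (_, sd) in params.items():
                if score not in SCORES:
                    raise ValueError(f"unknown clinical score {score!r}")
                if sd < 0:
                    raise ValueError("clinical SDs must be >= 0")

    def roi_labels(self) -> list[str]:
        full = aal116_labels()
        if self.n_rois <= 116:
            return full[: self.n_rois]
        return full + [f"ROI{k + 1:03d}" for k in range(116, self.n_rois)]

    def control_ids(self) -> list[str]:
        w = max(2, len(str(self.n_controls)))
        return [f"NC{k + 1:0{w}d}" for k in range(self.n_controls)]

    def patient_ids(self) -> list[str]:
        w = max(2, len(str(self.n_patients)))
        return [f"P{k + 1:0{w}d}" for k in range(self.n_patients)]


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery testing."""

    edge_states: dict[tuple[int, int], tuple[str, str, float]]
    group_target_matrices: dict[str, np.ndarray]
    clinical_coupling: dict[tuple[tuple[int, int], str], float]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted_edges": [
                {"i": i, "j": j, "state": st, "direction": d, "delta": dl}
                for (i, j), (st, d, dl) in sorted(self.edge_states.items())
            ],
            "clinical_coupling": [
                {"i": e[0], "j": e[1], "score": s, "rho": rho}
                for (e, s), rho in sorted(self.clinical_coupling.items())
            ],
            "group_target_matrices": {
                cond: m.tolist() for cond, m in self.group_target_matrices.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            edge_states={(e["i"], e["j"]): (e["state"], e["direction"], e["delta"])
                         for e in d["planted_edges"]},
            group_target_matrices={c: np.asarray(m, float)
                                   for c, m in d["group_target_matrices"].items()},
            clinical_coupling={((c["i"], c["j"]), c["score"]): c["rho"]
                               for c in d["clinical_coupling"]},
            seed=d["seed"],
        )


# ----------------------------------------------------------------- targets

def _repair_psd(m: np.ndarray, floor: float = _PSD_FLOOR) -> np.ndarray:
    """Clip eigenvalues at a small positive floor, renormalise unit diagonal."""
    w, v = np.linalg.eigh(m)
    if w.min() >= floor:
        return m.copy()
    w = np.clip(w, floor, None)
    a = (v * w) @ v.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def build_group_targets(config: SynthConfig,
                        ) -> tuple[dict[str, np.ndarray], SyntheticTruth]:
    """Per-condition target correlation matrices realising the planted states.

    For each planted edge the NC entry sits at its normal level and the
    abnormal conditions (per the state pattern) sit ``delta`` above or
    below it.  All three matrices are PSD-repaired before return; a repair
    that moves any planted entry by delta/10 or more raises, naming the
    offending edges.
    """
    config.validate()
    r = config.n_rois
    if np.isscalar(config.base_correlation):
        base = np.full((r, r), float(config.base_correlation))
        np.fill_diagonal(base, 1.0)
    else:
        base = np.asarray(config.base_correlation, float).copy()
    raw = {cond: base.copy() for cond in CONDITIONS}
    planned: dict[str, dict[tuple[int, int], float]] = {c: {} for c in CONDITIONS}
    for e in config.planted_edges:
        normal = float(base[e.i, e.j]) if e.normal_level is None else float(e.normal_level)
        shift = e.delta if e.direction == "increase" else -e.delta
        abnormal = normal + shift
        if not -1.0 < abnormal < 1.0 or not -1.0 < normal < 1.0:
            raise ValueError(f"planted edge {e.key}: target correlation outside (-1, 1)")
        per_cond = {
            "disorder": {"NC": normal, "IBSbs": abnormal, "IBS1st": abnormal},
            "cured": {"NC": normal, "IBSbs": abnormal, "IBS1st": normal},
            "activated": {"NC": normal, "IBSbs": normal, "IBS1st": abnormal},
        }[e.state]
        for cond, val in per_cond.items():
            raw[cond][e.i, e.j] = raw[cond][e.j, e.i] = val
            planned[cond][e.key] = val
    targets = {cond: _repair_psd(m) for cond, m in raw.items()}
    bad: list[tuple[int, int]] = []
    for e in config.planted_edges:
        tol = e.delta / 10.0 if e.delta > 0 else 1e-9
        for cond in CONDITIONS:
            if abs(targets[cond][e.i, e.j] - planned[cond][e.key]) >= tol:
                bad.append(e.key)
                break
    if bad:
        raise ValueError(
            "PSD repair distorted planted edges beyond delta/10 "
            f"(too many/large effects): {sorted(set(bad))}")
    truth = SyntheticTruth(
        edge_states={e.key: (e.state, e.direction, e.delta)
                     for e in config.planted_edges},
        group_target_matrices=targets,
        clinical_coupling={(tuple(edge), score): float(rho)
                           for (edge, score), rho in config.delta_coupling.items()},
        seed=config.seed,
    )
    return targets, truth


# -------------------------------------------------------------- time series

def _session_rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based substream: any subset of sessions is reproducible
    return np.random.default_rng([seed, stream])


def simulate_timeseries(targets: Mapping[str, np.ndarray],
                        config: SynthConfig) -> list[RoiTimeSeries]:
    """Draw every session's T x R series from its condition's target.

    Controls get one session ("single"); each patient two ("baseline"
    under the IBSbs target, "post" under IBS1st) with independent noise
    but a shared subject id.  Deterministic given the config seed.
    """
    config.validate()
    labels = config.roi_labels()
    t = config.n_timepoints
    chol = {}
    for cond in CONDITIONS:
        m = np.asarray(targets[cond], float)
        try:
            chol[cond] = np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            chol[cond] = np.linalg.cholesky(_repair_psd(m))
    sessions: list[RoiTimeSeries] = []
    for k, sid in enumerate(config.control_ids()):
        z = _session_rng(config.seed, k).standard_normal((t, config.n_rois))
        sessions.append(RoiTimeSeries(sid, "NC", "single",
                                      z @ chol["NC"].T, list(labels)))
    for k, sid in enumerate(config.patient_ids()):
        z = _session_rng(config.seed, 1_000_000 + k).standard_normal((t, config.n_rois))
        sessions.append(RoiTimeSeries(sid, "IBSbs", "baseline",
                                      z @ chol["IBSbs"].T, list(labels)))
        z = _session_rng(config.seed, 2_000_000 + k).standard_normal((t, config.n_rois))
        sessions.append(RoiTimeSeries(sid, "IBS1st", "post",
                                      z @ chol["IBS1st"].T, list(labels)))
    return sessions


# ----------------------------------------------------------------- clinical

def _realized_edge_deltas(sessions: Sequence[RoiTimeSeries],
                          edge: tuple[int, int],
                          patient_ids: Sequence[str]) -> np.ndarray:
    by_key = {(s.subject_id, s.session): s for s in sessions}
    i, j = edge
    out = np.empty(len(patient_ids))
    for k, pid in enumerate(patient_ids):
        try:
            pre = by_key[(pid, "baseline")]
            post = by_key[(pid, "post")]
        except KeyError:
            raise ValueError(f"patient {pid} lacks a baseline/post session pair")
        z_pre = np.arctanh(compute_fc(pre)[i, j])
        z_post = np.arctanh(compute_fc(post)[i, j])
        out[k] = z_post - z_pre
    return out


def simulate_clinical(config: SynthConfig,
                      sessions: Sequence[RoiTimeSeries] | None = None,
                      ) -> pd.DataFrame:
    """Per-subject clinical scores; long format, one row per session.

    Controls carry the anxiety score only (severity and quality-of-life
    cells are empty).  When a (edge, score) coupling rho is configured,
    the patient's score change is rho x the standardised realised Fisher-z
    change of that edge plus sqrt(1 - rho^2) x independent noise, rescaled
    to the configured between-session delta mean and SD; the generated
    time series are then required.
    """
    config.validate()
    if config.delta_coupling and sessions is None:
        raise ValueError("couplings configured: pass the generated sessions")
    rng = np.random.default_rng([config.seed, 3_000_000])
    params = {c: dict(config.clinical_params.get(c, {})) for c in CONDITIONS}
    coupled_scores = {score: tuple(edge)
                      for (edge, score) in config.delta_coupling}
    rows: list[dict] = []
    for sid in config.control_ids():
        row = {"subject_id": sid, "session": "single",
               "ibs_sss": np.nan, "ibs_qol": np.nan, "hama": np.nan}
        for score, (mean, sd) in params["NC"].items():
            row[score] = mean + sd * rng.standard_normal()
        rows.append(row)
    n = config.n_patients
    pids = config.patient_ids()
    draws: dict[tuple[str, str], np.ndarray] = {}
    for score in SCORES:
        p_bs = params["IBSbs"].get(score)
        p_1st = params["IBS1st"].get(score)
        if p_bs is None or p_1st is None:
            draws[("baseline", score)] = np.full(n, np.nan)
            draws[("post", score)] = np.full(n, np.nan)
            continue
        base = p_bs[0] + p_bs[1] * rng.standard_normal(n)
        if score in coupled_scores:
            edge = coupled_scores[score]
            rho = config.delta_coupling[(edge, score)]
            realized = _realized_edge_deltas(sessions, edge, pids)
            sd_r = realized.std()
            u = (realized - realized.mean()) / sd_r if sd_r > 0 else np.zeros(n)
            mix = rho * u + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
            d_mean = p_1st[0] - p_bs[0]
            d_sd = float(np.hypot(p_bs[1], p_1st[1]))
            post = base + d_mean + d_sd * mix
        else:
            post = p_1st[0] + p_1st[1] * rng.standard_normal(n)
        draws[("baseline", score)] = base
        draws[("post", score)] = post
    for k, pid in enumerate(pids):
        for sess in ("baseline", "post"):
            rows.append({"subject_id": pid, "session": sess,
                         **{s: draws[(sess, s)][k] for s in SCORES}})
    return pd.DataFrame(rows, columns=["subject_id", "session", *SCORES])


# ------------------------------------------------------------------- bundle

@dataclass
class CohortBundle:
    config: SynthConfig
    truth: SyntheticTruth
    sessions: list[RoiTimeSeries]
    design: pd.DataFrame
    clinical: pd.DataFrame


def _design_table(sessions: Sequence[RoiTimeSeries]) -> pd.DataFrame:
    rows = [{"subject_id": s.subject_id, "group": s.group, "session": s.session,
             "file": f"{s.subject_id}_{s.session}.tsv"} for s in sessions]
    return pd.DataFrame(rows, columns=["subject_id", "group", "session", "file"])


def simulate_cohort(config: SynthConfig) -> CohortBundle:
    """Full in-memory cohort: targets, time series, design, clinical, truth."""
    targets, truth = build_group_targets(config)
    sessions = simulate_timeseries(targets, config)
    clinical = simulate_clinical(config, sessions)
    return CohortBundle(config=config, truth=truth, sessions=sessions,
                        design=_design_table(sessions), clinical=clinical)


def generate_cohort(config: SynthConfig, outdir: str | Path) -> CohortBundle:
    """Generate the cohort and write its external-interface files.

    Layout under ``outdir``: one ``<subject>_<session>.tsv`` per session
    (T rows x R labelled columns), ``design.csv``, ``clinical.csv`` and
    ``truth.json``.  Identical configs produce byte-identical trees.
    """
    bundle = simulate_cohort(config)
    out = Path(outdir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for s in bundle.sessions:
        path = ts_dir / f"{s.subject_id}_{s.session}.tsv"
        try:
            header = "\t".join(s.roi_labels)
            np.savetxt(path, s.values, fmt="%.17g", delimiter="\t",
                       header=header, comments="")
        except OSError as exc:
            raise OSError(f"failed writing time series {path}: {exc}") from exc
    bundle.design.to_csv(out / "design.csv", index=False)
    bundle.clinical.to_csv(out / "clinical.csv", index=False, na_rep="")
    (out / "truth.json").write_text(
        json.dumps(bundle.truth.to_json_dict(), indent=1, sort_keys=True))
    return bundle


def load_cohort(outdir: str | Path) -> CohortBundle:
    """Reload a written cohort; inverse of :func:`generate_cohort`."""
    out = Path(outdir)
    design = pd.read_csv(out / "design.csv")
    clinical = pd.read_csv(out / "clinical.csv")
    truth = SyntheticTruth.from_json_dict(
        json.loads((out / "truth.json").read_text()))
    sessions = []
    for rec in design.itertuples(index=False):
        path = out / "timeseries" / rec.file
        if not path.exists():
            raise FileNotFoundError(f"missing time-series file {path}")
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        sessions.append(RoiTimeSeries(rec.subject_id, rec.group, rec.session,
                                      frame.to_numpy(float), list(frame.columns)))
    n_controls = int((design["group"] == "NC").sum())
    n_patients = int((design["session"] == "baseline").sum())
    r = sessions[0].n_rois if sessions else 0
    t = sessions[0].values.shape[0] if sessions else 0
    config = SynthConfig(n_controls=n_controls, n_patients=n_patients,
                         n_rois=r, n_timepoints=t, seed=truth.seed)
    return CohortBundle(config=config, truth=truth, sessions=sessions,
                        design=design, clinical=clinical)
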
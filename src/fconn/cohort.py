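"""Synthetic resting-state cohort generator.

Emulates the statistical structure of a three-group resting-state fMRI
study (healthy controls and two patient subtypes of functional
constipation, FCNAD/FCAD): 246-node ROI time series with a seven-module
community structure, six-parameter head-motion traces with occasional
spike frames, and per-group psychometric/symptom scores.

The generator draws ROI signals from a zero-mean multivariate Gaussian
whose correlation matrix is block-structured by functional module, with
configurable planted group effects for the patient groups:

* ``within_dropout`` — a seeded fraction of within-module region pairs is
  reduced to the between-module baseline, degrading clustered (modular)
  topology and hence the normalized clustering coefficient gamma and
  small-world-ness sigma of the binarized networks;
* ``block_shift`` — an additive shift on one inter-module block
  (by default salience-network-to-sensorimotor-network hyperconnectivity);
* ``node_scale`` — a multiplicative down-weighting of selected nodes'
  correlations (by default rostral-ACC-like and thalamus-like nodes),
  lowering their nodal degree/efficiency.

No spatial (voxel-level) data, scanner artifacts, or physiological noise
spectra are simulated: the downstream pipeline operates on ROI-level
signals only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("HC", "FCNAD", "FCAD")
PATIENT_GROUPS = ("FCNAD", "FCAD")

#: Default community sizes (seven functional modules).
DEFAULT_MODULE_SIZES = (50, 50, 48, 21, 22, 27, 28)
#: Short names for the default modules: frontoparietal, salience, default
#: mode, limbic, visual, sensorimotor, basal ganglia.
DEFAULT_MODULE_NAMES = ("FPN", "SN", "DMN", "LIM", "VIS", "SMN", "BG")

PSYCHOMETRIC_SCALES = ("sds", "sas", "sai", "tai")
SYMPTOM_SCALES = (
    "difficulty_defecation",
    "incomplete_evacuation",
    "abdominal_distension",
    "abdominal_pain",
)

# Per-group (mean, SE) for age, the four anxiety/depression scales, and —
# for the patient groups — the four constipation-symptom ratings.
DEFAULT_PSYCHOMETRICS: dict[str, dict[str, tuple[float, float]]] = {
    "HC": {
        "age": (38.0698, 2.0942),
        "sds": (37.3953, 1.1780),
        "sas": (33.4884, 1.0462),
        "sai": (28.3256, 1.2325),
        "tai": (30.0465, 1.1489),
    },
    "FCNAD": {
        "age": (42.7619, 2.0774),
        "sds": (44.7857, 1.0710),
        "sas": (41.3810, 1.0421),
        "sai": (33.6667, 1.5406),
        "tai": (36.3571, 1.4301),
        "difficulty_defecation": (67.9762, 3.1373),
        "incomplete_evacuation": (63.7619, 3.9184),
        "abdominal_distension": (44.6429, 4.6566),
        "abdominal_pain": (25.7857, 3.6878),
    },
    "FCAD": {
        "age": (38.6098, 1.8044),
        "sds": (69.0244, 1.4673),
        "sas": (63.7073, 1.5801),
        "sai": (57.3415, 1.5176),
        "tai": (55.2439, 1.2854),
        "difficulty_defecation": (71.6585, 3.6181),
        "incomplete_evacuation": (65.5366, 4.8007),
        "abdominal_distension": (63.5122, 4.6608),
        "abdominal_pain": (34.9024, 4.6353),
    },
}

#: Default male counts per group (the remainder of each group is female).
DEFAULT_MALE_COUNTS = {"HC": 18, "FCNAD": 16, "FCAD": 10}

# Valid ranges used to truncate psychometric draws.
SCALE_RANGES = {
    "sds": (25.0, 100.0),
    "sas": (25.0, 100.0),
    "sai": (20.0, 80.0),
    "tai": (20.0, 80.0),
    "age": (18.0, 75.0),
    **{s: (0.0, 100.0) for s in SYMPTOM_SCALES},
}


@dataclass(frozen=True)
class GroupEffect:
    """A planted group-level perturbation of the target correlation matrix.

    ``kind`` is one of ``"within_dropout"`` (reduce a random ``fraction``
    of within-module pairs to the between-module baseline),
    ``"block_shift"`` (add ``delta`` to the inter-module block between
    ``modules``), or ``"node_scale"`` (multiply the rows/columns of
    ``nodes`` by ``factor``).
    """

    kind: str
    groups: tuple[str, ...] = PATIENT_GROUPS
    fraction: float = 0.0
    modules: tuple[int, int] = (0, 0)
    delta: float = 0.0
    nodes: tuple[int, ...] = ()
    factor: float = 1.0

    def applies_to(self, group: str) -> bool:
        return group in self.groups


def default_effect_map(module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES) -> tuple[GroupEffect, ...]:
    """Planted patient effects: degraded modular clustering (lower gamma
    and sigma), SN-SMN inter-module hyperconnectivity, and reduced
    rACC/thalamus nodal connectivity. Node indices for the nodal effect
    are the first two nodes of the SN-like module (module 1) and of the
    basal-ganglia-like module (module 6), resolved from the parcellation."""
    bounds = np.concatenate([[0], np.cumsum(module_sizes)])
    n_mod = len(module_sizes)
    sn_mod = min(1, n_mod - 1)
    smn_mod = min(5, n_mod - 1)
    bg_mod = min(6, n_mod - 1)
    sn_start, bg_start = int(bounds[sn_mod]), int(bounds[bg_mod])
    return (
        GroupEffect(kind="within_dropout", fraction=0.12),
        # module index 1 = SN, 5 = SMN under the default parcellation
        GroupEffect(kind="block_shift", modules=(sn_mod, smn_mod), delta=0.10),
        # two rACC-like nodes inside the SN, two thalamus-like in the BG
        GroupEffect(
            kind="node_scale",
            nodes=(sn_start, sn_start + 1, bg_start, bg_start + 1),
            factor=0.80,
        ),
    )


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``group_sizes`` maps group label to subject count; ``module_sizes``
    are the planted community sizes (must sum to ``n_nodes``);
    ``within_r``/``between_r`` are the baseline within- and
    between-module Pearson correlation targets; ``psychometric_spec``
    holds per-group (mean, SE) pairs, with SE converted to an SD via
    SD = SE * sqrt(n).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 43, "FCNAD": 42, "FCAD": 41}
    )
    n_nodes: int = 246
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    module_names: tuple[str, ...] = DEFAULT_MODULE_NAMES
    n_frames: int = 195
    tr_seconds: float = 2.0
    within_r: float = 0.40
    between_r: float = 0.05
    effect_map: tuple[GroupEffect, ...] | None = None
    psychometric_spec: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PSYCHOMETRICS.items()}
    )
    male_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MALE_COUNTS))
    signal_sd: float = 2.0
    baseline: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()
        if self.effect_map is None:
            self.effect_map = default_effect_map(tuple(self.module_sizes))

    def validate(self) -> None:
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module sizes {self.module_sizes} sum to {sum(self.module_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not (abs(self.within_r) < 1 and abs(self.between_r) < 1):
            raise ValueError("|within_r| and |between_r| must be < 1")
        for group, spec in self.psychometric_spec.items():
            for scale, (_, se) in spec.items():
                if se <= 0:
                    raise ValueError(f"SE for {group}/{scale} must be positive")

    @property
    def module_slices(self) -> list[slice]:
        bounds = np.concatenate([[0], np.cumsum(self.module_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    @property
    def module_labels(self) -> np.ndarray:
        """Per-node planted module index."""
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    gender: str
    sds: float
    sas: float
    sai: float
    tai: float
    difficulty_defecation: float = np.nan
    incomplete_evacuation: float = np.nan
    abdominal_distension: float = np.nan
    abdominal_pain: float = np.nan

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for scale in SYMPTOM_SCALES:
            v = getattr(self, scale)
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{scale}={v} outside [0, 100]")


@dataclass
class RoiTimeSeriesSet:
    """Frames-by-nodes signal matrix for one subject."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    valid_mask: np.ndarray
    wm: np.ndarray | None = None
    csf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.valid_mask.shape[0] != self.data.shape[0]:
            raise ValueError("valid_mask length must match frame count")
        if not np.all(np.isfinite(self.data[self.valid_mask])):
            raise ValueError("non-finite values among valid frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Six rigid-body parameters per frame plus derived FD and DVARS."""

    params: np.ndarray  # frames x 6: 3 translations (mm), 3 rotations (rad)
    fd: np.ndarray
    dvars: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be frames x 6")
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if (self.fd < 0).any() or (self.dvars < 0).any():
            raise ValueError("fd and dvars must be non-negative")


def base_correlation(spec: CohortSpec) -> np.ndarray:
    """Block-structured target correlation matrix without group effects."""
    c = np.full((spec.n_nodes, spec.n_nodes), spec.between_r)
    for sl in spec.module_slices:
        c[sl, sl] = spec.within_r
    np.fill_diagonal(c, 1.0)
    return c


def _dropout_pairs(spec: CohortSpec, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Seeded selection of within-module node pairs for the dropout effect.

    Pair selection is a property of the cohort (derived from the cohort
    seed), so both patient groups share the same degraded pairs.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 1719])
    rows, cols = [], []
    for sl in spec.module_slices:
        idx = np.arange(sl.start, sl.stop)
        iu = np.triu_indices(len(idx), 1)
        rows.append(idx[iu[0]])
        cols.append(idx[iu[1]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n_pick = int(round(fraction * len(rows)))
    pick = rng.choice(len(rows), size=n_pick, replace=False)
    return rows[pick], cols[pick]


def nearest_positive_definite(c: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped projection to a positive-definite correlation
    matrix: eigenvalues below ``eig_floor`` are raised to it and the
    result is renormalized to unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2)
    w = np.maximum(w, eig_floor)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2


def target_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """Target correlation matrix for ``group``: block baseline plus any
    planted effects, repaired to positive definiteness if required."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    c = base_correlation(spec)
    for eff in spec.effect_map:
        if not eff.applies_to(group):
            continue
        if eff.kind == "within_dropout":
            r, s = _dropout_pairs(spec, eff.fraction)
            c[r, s] = spec.between_r
            c[s, r] = spec.between_r
        elif eff.kind == "block_shift":
            a, b = eff.modules
            sa, sb = spec.module_slices[a], spec.module_slices[b]
            c[sa, sb] += eff.delta
            c[sb, sa] += eff.delta
        elif eff.kind == "node_scale":
            nodes = list(eff.nodes)
            c[nodes, :] *= eff.factor
            c[:, nodes] *= eff.factor
            np.fill_diagonal(c, 1.0)
        else:
            raise ValueError(f"unknown effect kind {eff.kind!r}")
    np.fill_diagonal(c, 1.0)
    min_eig = float(np.linalg.eigvalsh(c).min())
    if min_eig < 1e-8:
        logger.warning(
            "target correlation for group %s not positive definite "
            "(min eigenvalue %.3e); repairing by eigenvalue clipping",
            group,
            min_eig,
        )
        c = nearest_positive_definite(c)
    return c


def generate_motion(
    n_frames: int,
    spike_frames: np.ndarray | list[int],
    seed: int,
    step_sd_mm: float = 0.01,
    step_sd_rad: float = 2e-4,
    spike_mm: float = 2.0,
) -> MotionTrace:
    """Six-parameter random-walk motion trace with displacement spikes.

    The walk has small per-frame steps (defaults give baseline FD well
    below the 0.5 mm scrubbing threshold); at each frame in
    ``spike_frames`` a ``spike_mm`` translation offset is applied for a
    single frame, producing a large framewise displacement there.
    """
    spike_frames = np.asarray(spike_frames, dtype=int)
    if spike_frames.size and (spike_frames.min() < 0 or spike_frames.max() >= n_frames):
        raise ValueError("spike frame indices out of range")
    rng = np.random.default_rng(seed)
    steps = np.empty((n_frames, 6))
    steps[:, :3] = rng.normal(0.0, step_sd_mm, (n_frames, 3))
    steps[:, 3:] = rng.normal(0.0, step_sd_rad, (n_frames, 3))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    params[spike_frames, 0] += spike_mm
    from .preprocess import compute_fd  # local import to avoid a cycle

    fd = compute_fd(params)
    return MotionTrace(params=params, fd=fd, dvars=np.zeros(n_frames))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, n), lo, hi)


def generate_subject_table(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectRecord]:
    """Demographics and psychometrics for every subject.

    Scale scores are drawn per group from Normal(mean, SE * sqrt(n)) and
    truncated to each scale's valid range; gender is assigned to match
    the configured per-group male counts exactly (scaled proportionally
    if the group size differs from the default)."""
    records: list[SubjectRecord] = []
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        pspec = spec.psychometric_spec[group]
        draws: dict[str, np.ndarray] = {}
        for scale in ("age", *PSYCHOMETRIC_SCALES, *SYMPTOM_SCALES):
            if scale not in pspec:
                draws[scale] = np.full(n, np.nan)
                continue
            mean, se = pspec[scale]
            default_n = {"HC": 43, "FCNAD": 42, "FCAD": 41}.get(group, n)
            sd = se * np.sqrt(default_n)
            lo, hi = SCALE_RANGES[scale]
            draws[scale] = _truncated_normal(rng, mean, sd, n, lo, hi)
        n_male_default = spec.male_counts.get(group, n // 2)
        default_n = {"HC": 43, "FCNAD": 42, "FCAD": 41}.get(group, n)
        n_male = n_male_default if n == default_n else int(round(n * n_male_default / default_n))
        gender = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(gender)
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    age=float(draws["age"][i]),
                    gender=str(gender[i]),
                    sds=float(draws["sds"][i]),
                    sas=float(draws["sas"][i]),
                    sai=float(draws["sai"][i]),
                    tai=float(draws["tai"][i]),
                    difficulty_defecation=float(draws["difficulty_defecation"][i]),
                    incomplete_evacuation=float(draws["incomplete_evacuation"][i]),
                    abdominal_distension=float(draws["abdominal_distension"][i]),
                    abdominal_pain=float(draws["abdominal_pain"][i]),
                )
            )
    return records


def _smooth_noise(rng: np.random.Generator, n: int, width: int = 5) -> np.ndarray:
    x = rng.standard_normal(n + width)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="valid")[:n]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], list[RoiTimeSeriesSet], list[MotionTrace]]:
    """Generate the full synthetic cohort.

    Signals are draws of white Gaussian noise colored by the Cholesky
    factor of each group's target correlation matrix, plus shared
    white-matter/CSF-like nuisance components, a random linear drift, a
    constant baseline offset, and co-occurring signal/motion spikes at a
    few random frames per subject. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records = generate_subject_table(spec, rng)
    chol = {g: np.linalg.cholesky(target_correlation(spec, g)) for g in GROUPS}
    trend = np.linspace(-0.5, 0.5, spec.n_frames)
    ts_sets: list[RoiTimeSeriesSet] = []
    motions: list[MotionTrace] = []
    for rec in records:
        n_spikes = int(rng.integers(0, 4))
        spike_frames = np.sort(
            rng.choice(np.arange(1, spec.n_frames), size=n_spikes, replace=False)
        )
        white = rng.standard_normal((spec.n_frames, spec.n_nodes))
        x = (white @ chol[rec.group].T) * spec.signal_sd
        wm = _smooth_noise(rng, spec.n_frames)
        csf = _smooth_noise(rng, spec.n_frames)
        x += np.outer(wm, np.full(spec.n_nodes, 0.3 * spec.signal_sd))
        x += np.outer(csf, np.full(spec.n_nodes, 0.2 * spec.signal_sd))
        x += np.outer(trend, rng.normal(0.0, 0.5 * spec.signal_sd, spec.n_nodes))
        if n_spikes:
            x[spike_frames] += rng.normal(0.0, 6 * spec.signal_sd, (n_spikes, spec.n_nodes))
        x += spec.baseline
        motion_seed = int(rng.integers(0, 2**31 - 1))
        motion = generate_motion(spec.n_frames, spike_frames, seed=motion_seed)
        from .preprocess import compute_dvars

        motion.dvars = compute_dvars(x)
        ts_sets.append(
            RoiTimeSeriesSet(
                subject_id=rec.subject_id,
                data=x,
                tr_seconds=spec.tr_seconds,
                valid_mask=np.ones(spec.n_frames, dtype=bool),
                wm=wm,
                csf=csf,
            )
        )
        motions.append(motion)
    return records, ts_sets, motions


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


# ---------------------------------------------------------------------------
# serialization

def write_cohort(
    outdir: str | Path,
    spec: CohortSpec,
    records: list[SubjectRecord],
    ts_sets: list[RoiTimeSeriesSet],
    motions: list[MotionTrace],
) -> Path:
    """Write the cohort as delimited text plus a JSON manifest."""
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(parents=True, exist_ok=True)
    table = subjects_to_frame(records)
    table.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    atlas = pd.DataFrame(
        {
            "node": np.arange(spec.n_nodes),
            "module_id": spec.module_labels,
            "module_name": np.asarray(spec.module_names)[spec.module_labels],
        }
    )
    atlas.to_csv(outdir / "atlas.tsv", sep="\t", index=False)
    manifest = {"seed": spec.seed, "tr_seconds": spec.tr_seconds, "subjects": {}}
    for rec, ts, mot in zip(records, ts_sets, motions):
        sig_path = outdir / "signals" / f"{rec.subject_id}.tsv"
        mot_path = outdir / "motion" / f"{rec.subject_id}.tsv"
        np.savetxt(sig_path, ts.data, delimiter="\t", fmt="%.6f")
        np.savetxt(mot_path, mot.params, delimiter="\t", fmt="%.8f")
        if ts.wm is not None:
            np.savetxt(
                outdir / "signals" / f"{rec.subject_id}_nuisance.tsv",
                np.column_stack([ts.wm, ts.csf]),
                delimiter="\t",
                fmt="%.6f",
                header="wm\tcsf",
                comments="",
            )
        manifest["subjects"][rec.subject_id] = {
            "signals": str(sig_path.relative_to(outdir)),
            "motion": str(mot_path.relative_to(outdir)),
        }
    manifest["spec"] = {
        "group_sizes": spec.group_sizes,
        "n_nodes": spec.n_nodes,
        "module_sizes": list(spec.module_sizes),
        "n_frames": spec.n_frames,
        "within_r": spec.within_r,
        "between_r": spec.between_r,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def read_cohort(
    indir: str | Path, tr_seconds: float | None = None
) -> tuple[pd.DataFrame, list[RoiTimeSeriesSet], list[MotionTrace]]:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    tr = tr_seconds if tr_seconds is not None else manifest.get("tr_seconds", 2.0)
    table = pd.read_csv(indir / "subjects.tsv", sep="\t")
    ts_sets, motions = [], []
    from .preprocess import compute_dvars, compute_fd

    for sid in table["subject_id"]:
        entry = manifest["subjects"][sid]
        data = pd.read_csv(indir / entry["signals"], sep="\t", header=None).to_numpy(float)
        params = pd.read_csv(indir / entry["motion"], sep="\t", header=None).to_numpy(float)
        nuis = indir / "signals" / f"{sid}_nuisance.tsv"
        wm = csf = None
        if nuis.exists():
            wmcsf = pd.read_csv(nuis, sep="\t").to_numpy(float)
            wm, csf = wmcsf[:, 0], wmcsf[:, 1]
        ts_sets.append(
            RoiTimeSeriesSet(
                subject_id=sid,
                data=data,
                tr_seconds=tr,
                valid_mask=np.ones(data.shape[0], dtype=bool),
                wm=wm,
                csf=csf,
            )
        )
        motions.append(
            MotionTrace(params=params, fd=compute_fd(params), dvars=compute_dvars(data))
        )
    return table, ts_sets, motions
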
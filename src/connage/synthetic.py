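"""Synthetic resting-state cohorts with age-dependent connectivity.

The generator emulates the statistical structure the downstream analysis
assumes: subjects drawn in age groups, three scans per subject, and a
planted subset of ROI-pair connectivity features whose mean depends
linearly on age in Fisher-z space.  For a planted ("informative") edge e
with slope beta_e (z-units per decade), a scan's value is

    z = baseline_z + beta_e * (age - 50) / 10 + u_(subject, e) + v_(scan, e)

with u ~ Normal(0, subject_sd) drawn once per subject and edge, and
v ~ Normal(0, scan_sd) fresh per scan and edge.  Non-informative edges lack
the age term.  Centring the age effect at 50 years keeps baseline_z the
cohort-typical connectivity for a middle-aged adult.

Ages are uniform within each group's range; sex alternates within a group
and carries no planted effect.  All randomness flows from a single integer
seed through named `numpy` sub-streams (one per subject), so regenerating
with the same spec is bit-identical and enlarging a cohort does not
reshuffle existing subjects.

Planted slopes alternate in sign across informative edges: healthy aging
strengthens some couplings and weakens others, and a sign-balanced truth
also exercises the classifier weights in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .connectome import (ROIAtlas, ScanTimeSeries, devectorize, n_features,
                         Connectome)


class SyntheticError(ValueError):
    pass


@dataclass
class GroupSpec:
    """One age group: subject count, inclusive age range, class label."""

    n_subjects: int
    age_low: float
    age_high: float
    label: str

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SyntheticError(
                f"group {self.label!r}: n_subjects must be >= 1")
        if self.age_low > self.age_high:
            raise SyntheticError(
                f"group {self.label!r}: age_low exceeds age_high")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; see the module docstring."""

    groups: list
    n_rois: int = 100
    n_volumes: int = 128
    tr: float = 2.0
    scans_per_subject: int = 3
    n_informative_edges: int = 50
    edge_effect: float = 0.1      # z-units per decade of age
    baseline_z: float = 0.3
    subject_sd: float = 0.25
    scan_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise SyntheticError("groups: at least one group required")
        if self.n_informative_edges > n_features(self.n_rois):
            raise SyntheticError(
                "n_informative_edges exceeds the number of ROI pairs")
        if self.n_informative_edges < 0:
            raise SyntheticError("n_informative_edges must be >= 0")
        if self.subject_sd < 0 or self.scan_sd < 0:
            raise SyntheticError("noise standard deviations must be >= 0")
        if self.tr <= 0:
            raise SyntheticError("tr must be positive")
        if self.scans_per_subject < 1:
            raise SyntheticError("scans_per_subject must be >= 1")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    @property
    def n_features(self) -> int:
        return n_features(self.n_rois)


@dataclass
class SyntheticCohort:
    """Generated cohort: subject table, scan table + connectome matrix,
    planted truth, and (optionally) rendered ROI time series."""

    spec: CohortSpec
    subjects: pd.DataFrame          # id, age, sex, group
    scans: pd.DataFrame             # subject_id, scan_index
    X: np.ndarray                   # n_scans x n_features z-values
    truth: pd.DataFrame             # feature_number, beta
    timeseries: list | None = field(default=None, repr=False)

    def connectome(self, scan_row: int) -> Connectome:
        return Connectome(self.X[scan_row], n_rois=self.spec.n_rois)

    def to_grouped_dataset(self, target: str = "group"):
        """GroupedDataset view for LOOCV; target in {group, age, sex}."""
        from .evaluation import GroupedDataset
        col = {"group": "group", "age": "age", "sex": "sex"}[target]
        per_subj = self.subjects.set_index("id")[col]
        y = per_subj.loc[self.scans["subject_id"]].to_numpy()
        return GroupedDataset(self.X, self.scans["subject_id"].to_numpy(),
                              y)

    def write(self, outdir) -> None:
        """Plain-text export: subjects.csv, truth.csv, per-scan z CSVs."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        feat = np.arange(1, self.spec.n_features + 1)
        for row, (sid, idx) in enumerate(
                zip(self.scans["subject_id"], self.scans["scan_index"])):
            pd.DataFrame({"feature_number": feat, "z": self.X[row]}).to_csv(
                out / f"connectome_{sid}_scan{idx}.csv", index=False)


# ---------------------------------------------------------------------------
# canned cohort layouts (the study's two datasets)

def young_old_spec(**overrides) -> CohortSpec:
    """Binary cohort: 26 young (19-35) + 26 old (55-85), 3 scans each."""
    spec = CohortSpec(groups=[GroupSpec(26, 19, 35, "young"),
                              GroupSpec(26, 55, 85, "old")])
    return replace(spec, **overrides) if overrides else spec


def three_group_spec(**overrides) -> CohortSpec:
    """Three-class cohort: 28 young (19-37), 22 middle (42-60),
    15 old (61-85)."""
    spec = CohortSpec(groups=[GroupSpec(28, 19, 37, "young"),
                              GroupSpec(22, 42, 60, "middle"),
                              GroupSpec(15, 61, 85, "old")])
    return replace(spec, **overrides) if overrides else spec


def edge_effect_for_cohens_d(spec: CohortSpec, d: float) -> float:
    """Slope (z/decade) giving subject-level Cohen's d between the first
    and last group of ``spec``.

    The d is computed on scan-averaged subject values: group-mean
    difference beta * (mean_age_b - mean_age_a) / 10 over the pooled
    within-group SD, which includes subject noise, scan noise reduced by
    averaging, and the age-spread contribution beta^2 Var(age) / 100 under
    the uniform age draw.
    """
    ga, gb = spec.groups[0], spec.groups[-1]
    mean_diff = abs((gb.age_low + gb.age_high) / 2
                    - (ga.age_low + ga.age_high) / 2)
    if mean_diff == 0:
        raise SyntheticError("groups share the same mean age")
    var_age = ((ga.age_high - ga.age_low) ** 2 / 12
               + (gb.age_high - gb.age_low) ** 2 / 12) / 2
    v0 = spec.subject_sd ** 2 + spec.scan_sd ** 2 / spec.scans_per_subject
    denom = mean_diff ** 2 - d ** 2 * var_age
    if denom <= 0:
        raise SyntheticError(
            f"d={d} unreachable for this group layout (age spread too "
            "large relative to the group separation)")
    return 10.0 * d * np.sqrt(v0 / denom)


# ---------------------------------------------------------------------------
# generation

def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from ``spec``; deterministic given ``spec.seed``."""
    master = np.random.SeedSequence(spec.seed)
    # stream 0: planted-edge choice; streams 1..n_subjects: per subject
    edge_ss, *subject_ss = master.spawn(1 + spec.n_subjects)

    nfeat = spec.n_features
    rng_edges = np.random.default_rng(edge_ss)
    informative = np.sort(rng_edges.choice(
        nfeat, size=spec.n_informative_edges, replace=False)) + 1
    betas = spec.edge_effect * np.where(
        np.arange(spec.n_informative_edges) % 2 == 0, 1.0, -1.0)
    truth = pd.DataFrame({"feature_number": informative, "beta": betas})

    slopes = np.zeros(nfeat)
    slopes[informative - 1] = betas

    subj_rows = []
    scan_rows = []
    X = np.empty((spec.n_subjects * spec.scans_per_subject, nfeat))
    row = 0
    subj_i = 0
    for group in spec.groups:
        group_rows = []
        for _ in range(group.n_subjects):
            ss = subject_ss[subj_i]
            rng = np.random.default_rng(ss)
            age = rng.uniform(group.age_low, group.age_high)
            sid = f"sub-{subj_i + 1:03d}"
            group_rows.append({"id": sid, "age": age,
                               "group": group.label})
            mean = (spec.baseline_z + slopes * (age - 50.0) / 10.0
                    + rng.normal(0.0, spec.subject_sd, size=nfeat))
            for scan in range(spec.scans_per_subject):
                X[row] = mean + rng.normal(0.0, spec.scan_sd, size=nfeat)
                scan_rows.append({"subject_id": sid, "scan_index": scan + 1})
                row += 1
            subj_i += 1
        # sex alternates within the group in age order: the sexes come out
        # age-matched, so a null gender analysis really is null (no age
        # confound from a chance M/F age imbalance)
        by_age = sorted(range(len(group_rows)),
                        key=lambda r: group_rows[r]["age"])
        for rank, r in enumerate(by_age):
            group_rows[r]["sex"] = "M" if rank % 2 == 0 else "F"
        subj_rows.extend({"id": g["id"], "age": g["age"], "sex": g["sex"],
                          "group": g["group"]} for g in group_rows)

    subjects = pd.DataFrame(subj_rows)
    scans = pd.DataFrame(scan_rows)
    cohort = SyntheticCohort(spec=spec, subjects=subjects, scans=scans,
                             X=X, truth=truth)
    _check_cohort(cohort)
    return cohort


def _check_cohort(c: SyntheticCohort) -> None:
    spec = c.spec
    assert len(c.subjects) == spec.n_subjects
    assert len(c.scans) == spec.n_subjects * spec.scans_per_subject
    counts = c.scans["subject_id"].value_counts()
    assert (counts == spec.scans_per_subject).all()
    for group in spec.groups:
        sel = c.subjects[c.subjects["group"] == group.label]
        assert len(sel) == group.n_subjects
        assert sel["age"].between(group.age_low, group.age_high).all()
    if len(c.truth):
        assert c.truth["feature_number"].between(1, spec.n_features).all()


# ---------------------------------------------------------------------------
# rendering: z-vectors -> ROI time series -> 4D volumes

def render_timeseries(cohort: SyntheticCohort,
                      n_volumes: int | None = None) -> SyntheticCohort:
    """Attach per-scan ROI time series whose sample correlation matrix
    approximates tanh of the scan's planted z-matrix.

    The target correlation matrix is projected to the nearest valid
    correlation matrix before factorisation (planted z-vectors need not be
    positive definite); series are Gaussian, so the approximation error
    shrinks as 1/sqrt(n_volumes).
    """
    spec = cohort.spec
    T = n_volumes or spec.n_volumes
    master = np.random.SeedSequence((spec.seed, 7))  # distinct stream family
    streams = master.spawn(len(cohort.scans))
    series = []
    for row in range(len(cohort.scans)):
        target = np.tanh(devectorize(cohort.connectome(row)))
        np.fill_diagonal(target, 1.0)
        if target.shape[0] > 1:
            target = corr_nearest(target, threshold=1e-10)
        vals, vecs = np.linalg.eigh(target)
        if np.min(vals) < -1e-8:
            sid = cohort.scans["subject_id"].iloc[row]
            raise SyntheticError(
                f"scan {sid}/{cohort.scans['scan_index'].iloc[row]}: "
                "target not positive semidefinite after projection")
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        rng = np.random.default_rng(streams[row])
        ts = L @ rng.standard_normal((spec.n_rois, T))
        series.append(ScanTimeSeries(ts, tr=spec.tr))
    cohort.timeseries = series
    return cohort


def render_volumes(cohort: SyntheticCohort, atlas: ROIAtlas,
                   grid_shape=(24, 24, 24), voxel_size_mm: float = 3.0,
                   voxel_noise_sd: float = 0.0) -> list:
    """One 4D NIfTI image per scan: sphere voxels carry the ROI series
    plus optional voxel noise; background is pure noise.

    The affine maps voxel indices to mm with the grid centred on the
    origin, so atlas coordinates near (0, 0, 0) land mid-grid.  Raises if
    any atlas sphere does not fit inside the grid.
    """
    import nibabel as nib

    if cohort.timeseries is None:
        raise SyntheticError("render_timeseries must be called first")
    shape = tuple(int(s) for s in grid_shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0

    extent_lo = affine[:3, 3] - voxel_size_mm / 2
    extent_hi = extent_lo + voxel_size_mm * np.array(shape)
    for idx, (center, radius, name) in enumerate(zip(
            atlas.centers, atlas.table["radius"], atlas.names)):
        if np.any(center - radius < extent_lo) or \
                np.any(center + radius > extent_hi):
            raise SyntheticError(
                f"ROI {idx + 1} ({name}): sphere extends outside the grid")

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(),
                    np.ones(ii.size)], axis=0)
    mm = (affine @ vox)[:3].T

    master = np.random.SeedSequence((cohort.spec.seed, 13))
    streams = master.spawn(len(cohort.scans))
    images = []
    for row, ts in enumerate(cohort.timeseries):
        T = ts.n_volumes
        rng = np.random.default_rng(streams[row])
        data = rng.normal(0.0, max(voxel_noise_sd, 1e-3),
                          size=(np.prod(shape), T))
        for r, (center, radius) in enumerate(zip(atlas.centers,
                                                 atlas.table["radius"])):
            inside = np.sum((mm - center) ** 2, axis=1) <= float(radius) ** 2
            if not inside.any():
                raise SyntheticError(
                    f"ROI {r + 1}: sphere contains no voxel centre")
            noise = rng.normal(0.0, voxel_noise_sd,
                               size=(int(inside.sum()), T)) \
                if voxel_noise_sd > 0 else 0.0
            data[inside] = ts.values[r] + noise
        img = nib.Nifti1Image(
            data.reshape(*shape, T).astype(np.float32), affine)
        img.header.set_zooms((voxel_size_mm,) * 3 + (cohort.spec.tr,))
        images.append(img)
    return images


def synthetic_atlas(n_rois: int = 100, radius: float = 5.0,
                    spacing: float = 16.0) -> ROIAtlas:
    """Synthetic stand-in atlas: n_rois spheres on a regular 3-D lattice.

    This is NOT the published 100-ROI coordinate set (which is not printed
    in full anywhere this package can read); it provides geometrically
    valid, well-separated sphere centres for end-to-end testing of the
    volume pipeline.
    """
    side = int(np.ceil(n_rois ** (1 / 3)))
    coords = []
    for a in range(side):
        for b in range(side):
            for c in range(side):
                coords.append((a, b, c))
                if len(coords) == n_rois:
                    break
            if len(coords) == n_rois:
                break
        if len(coords) == n_rois:
            break
    coords = (np.array(coords, dtype=float) - (side - 1) / 2) * spacing
    networks = ["default", "cingulo-opercular", "fronto-parietal",
                "sensorimotor"]
    table = pd.DataFrame({
        "index": np.arange(1, n_rois + 1),
        "name": [f"synthetic_roi_{i:03d}" for i in range(1, n_rois + 1)],
        "network": [networks[i % 4] for i in range(n_rois)],
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "radius": radius,
    })
    return ROIAtlas(table)
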
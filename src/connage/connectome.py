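"""From 4D image or ROI time series to the canonical 4950-feature connectome.

The connectome of one resting-state scan is the vector of pairwise Pearson
correlations between ROI-averaged BOLD time series, Fisher-z transformed,
taken from the strict lower triangle of the ROI-by-ROI correlation matrix.
With 100 ROIs this gives 100*99/2 = 4950 features.

Feature-number convention
-------------------------
Features are numbered 1..n(n-1)/2 by enumerating the strict lower triangle
in column-major order: column 1 top-to-bottom, then column 2, and so on.
For a pair (i, j) with i > j (1-based ROI indices) the feature number is

    k(i, j) = (j - 1) * n - j * (j - 1) / 2 + (i - j).

This convention is fixed: it is the one under which published connectome
feature tables (e.g. ROI pair (60, 7) -> feature 632 at n = 100) are
reproduced, and every table written by this package uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConnectomeError(ValueError):
    pass


CONVENTION = "lower-triangular, column-major, 1-based"

#: inclusive band edges of the resting-state frequency band (Hz)
DEFAULT_LOW_HZ = 0.005
DEFAULT_HIGH_HZ = 0.1

_FISHER_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# atlas

@dataclass
class ROIAtlas:
    """Set of spherical ROIs in MNI millimetre space.

    ``table`` columns: index (1-based, contiguous), name (unique), network,
    x, y, z (mm), radius (mm, default 5).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["index", "name", "network", "x", "y", "z", "radius"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ConnectomeError(f"atlas missing columns {missing}")
        idx = np.asarray(self.table["index"])
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ConnectomeError("atlas indices must be contiguous 1..N")
        if self.table["name"].duplicated().any():
            raise ConnectomeError("atlas ROI names must be unique")
        if (self.table["radius"] <= 0).any():
            raise ConnectomeError("atlas radii must be positive")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def centers(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @classmethod
    def from_csv(cls, path) -> "ROIAtlas":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        if "radius" not in df.columns:
            df["radius"] = 5.0
        if "network" not in df.columns:
            df["network"] = ""
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# time series

@dataclass
class ScanTimeSeries:
    """ROI-averaged BOLD series: ``values`` is n_rois x n_volumes, TR in s."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConnectomeError("time series must be 2-D (rois x volumes)")
        if not np.all(np.isfinite(self.values)):
            raise ConnectomeError("time series contains non-finite values")
        if self.values.shape[1] < 8:
            raise ConnectomeError("need at least 8 volumes")
        if self.tr <= 0:
            raise ConnectomeError("tr must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


def extract_roi_timeseries(image4d, atlas: ROIAtlas, tr: float | None = None
                           ) -> ScanTimeSeries:
    """Average the 4D image over each atlas sphere.

    A voxel belongs to an ROI when its centre lies within the sphere radius
    (Euclidean distance in mm, via the image affine).  ``tr`` defaults to the
    pixdim[4] recorded in the NIfTI header.
    """
    affine = getattr(image4d, "affine", None)
    if affine is None:
        raise ConnectomeError("image has no voxel-to-mm affine")
    data = np.asanyarray(image4d.dataobj)
    if data.ndim != 4:
        raise ConnectomeError("expected a 4D image")
    if tr is None:
        zooms = image4d.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0

    nx, ny, nz, nt = data.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(),
                    np.ones(ii.size)], axis=0)
    mm = (affine @ vox)[:3].T  # voxel centres in mm

    flat = data.reshape(-1, nt)
    series = np.empty((atlas.n_rois, nt))
    for r, (center, radius, name) in enumerate(zip(
            atlas.centers, atlas.table["radius"], atlas.names)):
        inside = np.sum((mm - center) ** 2, axis=1) <= float(radius) ** 2
        if not inside.any():
            raise ConnectomeError(
                f"ROI {r + 1} ({name}): sphere contains no voxel centre")
        series[r] = flat[inside].mean(axis=0)
    return ScanTimeSeries(series, tr=tr)


def detrend(ts: ScanTimeSeries) -> ScanTimeSeries:
    """Remove per-ROI linear and quadratic trends (least squares).

    The output of each ROI is orthogonal to span{1, t, t^2}; applying the
    operation twice changes nothing (it is an orthogonal projection).
    """
    n = ts.n_volumes
    t = np.linspace(-1.0, 1.0, n)  # scaled for conditioning
    basis = np.stack([np.ones(n), t, t * t], axis=1)
    qmat, _ = np.linalg.qr(basis)
    fitted = (ts.values @ qmat) @ qmat.T
    return ScanTimeSeries(ts.values - fitted, tr=ts.tr)


def bandpass(ts: ScanTimeSeries, low_hz: float = DEFAULT_LOW_HZ,
             high_hz: float = DEFAULT_HIGH_HZ) -> ScanTimeSeries:
    """Ideal frequency-domain band-pass with inclusive band edges.

    Retains DFT components with ``low_hz <= f <= high_hz``; everything else,
    including the DC component, is zeroed, so each filtered series has mean
    ~0.  Requires ``high_hz`` below the Nyquist frequency 1/(2 TR).
    """
    nyquist = 0.5 / ts.tr
    if high_hz >= nyquist:
        raise ConnectomeError(
            f"high edge {high_hz} Hz is not below Nyquist {nyquist} Hz")
    if low_hz < 0 or low_hz > high_hz:
        raise ConnectomeError("need 0 <= low_hz <= high_hz")
    freqs = np.fft.rfftfreq(ts.n_volumes, d=ts.tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    if not keep.any():
        raise ConnectomeError(
            f"band [{low_hz}, {high_hz}] Hz resolves no frequency at "
            f"{ts.n_volumes} volumes, TR={ts.tr}s")
    spec = np.fft.rfft(ts.values, axis=1)
    spec[:, ~keep] = 0.0
    return ScanTimeSeries(np.fft.irfft(spec, n=ts.n_volumes, axis=1),
                          tr=ts.tr)


def correlation_matrix(ts: ScanTimeSeries) -> np.ndarray:
    """Pearson correlation of every ROI pair; symmetric with unit diagonal."""
    sd = ts.values.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ConnectomeError(
            f"ROI {bad[0] + 1} has zero variance; correlation undefined")
    r = np.atleast_2d(np.corrcoef(ts.values))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher's variance-stabilising transform z = arctanh(r).

    ``|r|`` is clipped to 1 - 1e-7 so that perfectly correlated (degenerate)
    inputs stay finite.  Accepts scalars or arrays; raises if ``|r| > 1``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ConnectomeError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -_FISHER_CLIP, _FISHER_CLIP))
    return float(out) if np.isscalar(r) else out


# ---------------------------------------------------------------------------
# vectorization and feature numbering

@dataclass
class Connectome:
    """One scan's Fisher-z connectivity vector under the fixed convention."""

    z: np.ndarray
    n_rois: int
    convention: str = field(default=CONVENTION)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        expect = self.n_rois * (self.n_rois - 1) // 2
        if self.z.size != expect:
            raise ConnectomeError(
                f"expected {expect} features for {self.n_rois} ROIs, "
                f"got {self.z.size}")
        if not np.all(np.isfinite(self.z)):
            raise ConnectomeError("connectome contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.z.size


def n_features(n_rois: int) -> int:
    return n_rois * (n_rois - 1) // 2


def feature_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based (i, j) ROI indices of every feature, in feature order."""
    ju, iu = np.triu_indices(n_rois, k=1)  # row-major upper == our order
    return iu + 1, ju + 1


def pair_to_feature(i: int, j: int, n_rois: int) -> int:
    """Feature number of ROI pair (i, j), i > j, both 1-based."""
    if not (1 <= j < i <= n_rois):
        raise ConnectomeError(f"need 1 <= j < i <= n_rois, got ({i}, {j})")
    return (j - 1) * n_rois - j * (j - 1) // 2 + (i - j)


def feature_to_pair(k: int, n_rois: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_feature`."""
    total = n_features(n_rois)
    if not (1 <= k <= total):
        raise ConnectomeError(f"feature number {k} outside 1..{total}")
    j = 1
    offset = 0
    while offset + (n_rois - j) < k:
        offset += n_rois - j
        j += 1
    return j + (k - offset), j


def vectorize(matrix: np.ndarray, values: str = "r",
              atol: float = 1e-8) -> Connectome:
    """Strict lower triangle of a symmetric matrix as a Connectome.

    ``values="r"`` treats entries as correlations and applies the Fisher
    transform; ``values="z"`` passes them through unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeError("input must be square")
    if np.max(np.abs(m - m.T)) > atol:
        raise ConnectomeError("input matrix is not symmetric")
    n = m.shape[0]
    i1, j1 = feature_pairs(n)
    vals = m[i1 - 1, j1 - 1]
    if values == "r":
        vals = fisher_z(vals)
    elif values != "z":
        raise ConnectomeError("values must be 'r' or 'z'")
    return Connectome(vals, n_rois=n)


def devectorize(conn: Connectome) -> np.ndarray:
    """Symmetric z-matrix (zero diagonal) from a Connectome."""
    n = conn.n_rois
    out = np.zeros((n, n))
    i1, j1 = feature_pairs(n)
    out[i1 - 1, j1 - 1] = conn.z
    out[j1 - 1, i1 - 1] = conn.z
    return out


def build_connectome(ts: ScanTimeSeries, *, filter_band: bool = True,
                     remove_trends: bool = True) -> Connectome:
    """Full chain: (detrend, band-pass,) correlate, Fisher-z, vectorize."""
    if remove_trends:
        ts = detrend(ts)
    if filter_band:
        ts = bandpass(ts)
    return vectorize(correlation_matrix(ts), values="r")


def connectome_table(conn: Connectome, atlas: ROIAtlas | None = None
                     ) -> pd.DataFrame:
    """Long-format table: feature_number, roi_i, roi_j, (names,) r, z."""
    i1, j1 = feature_pairs(conn.n_rois)
    df = pd.DataFrame({
        "feature_number": np.arange(1, conn.n_features + 1),
        "roi_i": i1,
        "roi_j": j1,
        "r": np.tanh(conn.z),
        "z": conn.z,
    })
    if atlas is not None:
        names = atlas.names
        df.insert(3, "roi_i_name", [names[i - 1] for i in i1])
        df.insert(4, "roi_j_name", [names[j - 1] for j in j1])
    return df
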
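"""FAIR-ASL stage: per-pixel inversion-recovery T1 fitting, perfusion-map
computation, physiological thresholding and ROI summaries.

Perfusion quantification follows the classic FAIR relation

    f = 6000 * lambda * (1/T1_sel - 1/T1_ns)      [R1 in 1/s]

where ``lambda`` is the blood-tissue partition coefficient (ml/g,
default 0.9), T1_sel the apparent T1 under slice-selective inversion
(shortened by inflowing unlabelled blood) and T1_ns the global T1 under
non-selective inversion; 6000 converts 1/s * ml/g to ml/min/100 g.
Internally T1 is carried in milliseconds, so the constant becomes 6e6.

The inversion-recovery model is the 3-parameter magnitude-agnostic form

    S(TI) = M0 * (1 - B * exp(-TI/T1))

with B ~ 2 for perfect inversion; B is fitted because a finite TR leaves
the magnetization incompletely recovered.  Fitting uses variable
projection: for fixed T1 the model is linear in (M0, M0*B), so the
search is a fast 1-D grid + zoom over T1, fully vectorized over pixels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "IRSeries", "T1Map", "PerfusionMap", "ROISummary",
    "fit_t1_ir", "compute_t1_map", "compute_perfusion_map",
    "threshold_map", "roi_summary",
    "save_ir_series", "load_ir_series", "save_map", "load_mask",
    "FAIR_CONST_PER_MS", "T1_FIT_RANGE_MS",
]

logger = logging.getLogger(__name__)

#: 6000 (s, ml/g -> ml/min/100 g) expressed for T1 in milliseconds
FAIR_CONST_PER_MS = 6.0e6

#: physiological T1 window, ms; fits outside it are flagged invalid
T1_FIT_RANGE_MS = (50.0, 5000.0)

#: plausible inversion-efficiency window for the fitted B factor
B_VALID_RANGE = (1.0, 2.2)


@dataclass
class IRSeries:
    """An inversion-recovery stack: one 2-D frame per inversion time."""

    inversion_times: np.ndarray          # ms, strictly increasing
    frames: np.ndarray                   # (n_TI, H, W)
    labeling: str                        # "selective" | "nonselective"
    magnitude_data: bool = True

    def __post_init__(self) -> None:
        self.inversion_times = np.asarray(self.inversion_times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_TI, H, W)")
        if len(self.inversion_times) != self.frames.shape[0]:
            raise ValueError("frame count must equal TI count")
        if np.any(self.inversion_times <= 0) or np.any(np.diff(self.inversion_times) <= 0):
            raise ValueError("inversion times must be positive and strictly increasing")
        if self.labeling not in ("selective", "nonselective"):
            raise ValueError(f"labeling must be selective|nonselective, got {self.labeling!r}")


@dataclass
class T1Map:
    """Per-pixel longitudinal relaxation map with fit diagnostics."""

    t1: np.ndarray       # ms
    m0: np.ndarray       # equilibrium signal, a.u.
    b: np.ndarray        # inversion-recovery amplitude factor (~2)
    fit_ok: np.ndarray   # bool


@dataclass
class PerfusionMap:
    """Per-pixel perfusion, ml/min/100 g, with validity mask."""

    f: np.ndarray
    valid_mask: np.ndarray
    lambda_partition: float = 0.9


# ---------------------------------------------------------------------------
# variable-projection IR fitting
# ---------------------------------------------------------------------------

def _vp_solve(sig: np.ndarray, tis: np.ndarray, t1: np.ndarray):
    """Linear-part solution and SSE of S ~ a + c*exp(-TI/T1).

    sig: (n_ti, n_pix); t1: (n_pix, k) candidate T1s per pixel.
    Returns (sse, a, c), each (n_pix, k).
    """
    n_ti = len(tis)
    e = np.exp(-tis[:, None, None] / t1[None, :, :])       # (n_ti, n_pix, k)
    s1 = e.sum(axis=0)
    s2 = (e * e).sum(axis=0)
    sy = sig.sum(axis=0)[:, None]
    sey = np.einsum("ip,ipk->pk", sig, e)
    syy = (sig * sig).sum(axis=0)[:, None]
    det = n_ti * s2 - s1 * s1
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    a = (s2 * sy - s1 * sey) / det
    c = (n_ti * sey - s1 * sy) / det
    sse = syy - (a * sy + c * sey)
    return sse, a, c


def _polarity_candidates(sig: np.ndarray) -> np.ndarray:
    """Signed-data candidates for magnitude IR traces.

    For each pixel the null point is located at the TI of minimum
    magnitude; all earlier samples are negated.  Shifting the null point
    by ±1 sample gives three candidates (n_cand, n_ti, n_pix); the
    lowest-residual fit wins.
    """
    n_ti, n_pix = sig.shape
    i0 = np.argmin(np.abs(sig), axis=0)                    # (n_pix,)
    idx = np.arange(n_ti)[:, None]
    cands = []
    for shift in (-1, 0, 1):
        null = np.clip(i0 + shift, 0, n_ti)
        signs = np.where(idx < null[None, :], -1.0, 1.0)
        cands.append(sig * signs)
    return np.stack(cands)


def _fit_t1_stack(sig: np.ndarray, tis: np.ndarray, magnitude_data: bool,
                  n_grid: int = 128, n_zoom: int = 17, zoom_rounds: int = 3):
    """Vectorized 3-parameter IR fit of many traces.

    sig: (n_ti, n_pix).  Returns (t1, m0, b, fit_ok), each (n_pix,).
    """
    n_ti, n_pix = sig.shape
    lo, hi = T1_FIT_RANGE_MS
    variance = sig.var(axis=0)
    degenerate = variance <= 0

    if magnitude_data:
        datasets = _polarity_candidates(sig)
    else:
        datasets = sig[None, :, :]
    n_cand = datasets.shape[0]

    # coarse log grid, shared across pixels
    grid = np.geomspace(lo, hi, n_grid)
    best_sse = np.full(n_pix, np.inf)
    best_j = np.zeros(n_pix, dtype=int)
    best_cand = np.zeros(n_pix, dtype=int)
    t1_grid = np.broadcast_to(grid[None, :], (n_pix, n_grid))
    for ci in range(n_cand):
        sse, _, _ = _vp_solve(datasets[ci], tis, t1_grid)
        sse = np.where(np.isnan(sse), np.inf, sse)
        j = np.argmin(sse, axis=1)
        s = sse[np.arange(n_pix), j]
        better = s < best_sse
        best_sse = np.where(better, s, best_sse)
        best_j = np.where(better, j, best_j)
        best_cand = np.where(better, ci, best_cand)

    # per-pixel winning signed data
    signed = datasets[best_cand, :, np.arange(n_pix)].T     # (n_ti, n_pix)

    # zoom: shrink a per-pixel bracket around the coarse argmin
    t_lo = grid[np.maximum(best_j - 1, 0)]
    t_hi = grid[np.minimum(best_j + 1, n_grid - 1)]
    for _ in range(zoom_rounds):
        frac = np.linspace(0.0, 1.0, n_zoom)
        t1_cand = t_lo[:, None] + (t_hi - t_lo)[:, None] * frac[None, :]
        sse, _, _ = _vp_solve(signed, tis, t1_cand)
        sse = np.where(np.isnan(sse), np.inf, sse)
        j = np.argmin(sse, axis=1)
        jm = np.clip(j, 1, n_zoom - 2)
        new_lo = t1_cand[np.arange(n_pix), jm - 1]
        new_hi = t1_cand[np.arange(n_pix), jm + 1]
        t_lo, t_hi = new_lo, new_hi

    # parabolic refinement through the final three bracket points
    t1_cand = np.stack([t_lo, 0.5 * (t_lo + t_hi), t_hi], axis=1)
    sse3, _, _ = _vp_solve(signed, tis, t1_cand)
    y0, y1, y2 = sse3[:, 0], sse3[:, 1], sse3[:, 2]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -1.0, 1.0), 0.0)
    t1 = 0.5 * (t_lo + t_hi) + shift * 0.5 * (t_hi - t_lo)

    sse_f, a, c = _vp_solve(signed, tis, t1[:, None])
    m0 = a[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = -c[:, 0] / m0
    fit_ok = (
        np.isfinite(t1) & np.isfinite(m0) & np.isfinite(b)
        & (t1 > lo) & (t1 < hi) & (m0 > 0)
        & (b >= B_VALID_RANGE[0]) & (b <= B_VALID_RANGE[1])
        & ~degenerate
    )
    return t1, m0, b, fit_ok


def fit_t1_ir(signal: np.ndarray, inversion_times: np.ndarray,
              magnitude_data: bool = True):
    """Fit S(TI) = M0*(1 - B*exp(-TI/T1)) to one trace.

    Returns ``(t1_ms, m0, b, fit_ok)``.  For magnitude data the signal
    polarity is restored before fitting (null-point search with ±1-sample
    shifts, lowest residual kept).

    Raises on fewer than 4 distinct TIs or a constant trace (no
    relaxation information).
    """
    tis = np.asarray(inversion_times, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if len(np.unique(tis)) < 4:
        raise ValueError("need at least 4 distinct inversion times")
    if sig.shape != tis.shape:
        raise ValueError("signal and inversion_times must have equal length")
    if np.ptp(sig) == 0:
        raise ValueError("constant signal carries no relaxation information")
    t1, m0, b, ok = _fit_t1_stack(sig[:, None], tis, magnitude_data)
    return float(t1[0]), float(m0[0]), float(b[0]), bool(ok[0])


def compute_t1_map(series: IRSeries) -> T1Map:
    """Per-pixel T1 fit of an IR stack; failed pixels are flagged, never
    interpolated."""
    n_ti, h, w = series.frames.shape
    sig = series.frames.reshape(n_ti, h * w)
    t1, m0, b, ok = _fit_t1_stack(sig, series.inversion_times, series.magnitude_data)
    return T1Map(t1=t1.reshape(h, w), m0=m0.reshape(h, w),
                 b=b.reshape(h, w), fit_ok=ok.reshape(h, w))


# ---------------------------------------------------------------------------
# perfusion
# ---------------------------------------------------------------------------

def compute_perfusion_map(t1_selective: T1Map, t1_nonselective: T1Map,
                          lambda_partition: float = 0.9) -> PerfusionMap:
    """FAIR perfusion from the selective/non-selective apparent-T1 pair.

    f = 6e6 * lambda * (1/T1_sel - 1/T1_ns) with T1 in ms gives f in
    ml/min/100 g.  The output is unthresholded; validity is the AND of
    the two fit masks.
    """
    if t1_selective.t1.shape != t1_nonselective.t1.shape:
        raise ValueError("selective and non-selective maps are on different grids")
    if lambda_partition <= 0:
        raise ValueError("lambda_partition must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = FAIR_CONST_PER_MS * lambda_partition * (
            1.0 / t1_selective.t1 - 1.0 / t1_nonselective.t1)
    valid = t1_selective.fit_ok & t1_nonselective.fit_ok & np.isfinite(f)
    return PerfusionMap(f=f, valid_mask=valid, lambda_partition=lambda_partition)


def threshold_map(pmap: PerfusionMap, lo: float = 0.0, hi: float = 500.0) -> PerfusionMap:
    """Reject physiologically impossible perfusion values.

    Pixels outside [lo, hi] ml/min/100 g (vessels, noise) are removed
    from the validity mask; surviving values are untouched.
    """
    keep = pmap.valid_mask & (pmap.f >= lo) & (pmap.f <= hi)
    n_rejected = int(pmap.valid_mask.sum() - keep.sum())
    logger.info("threshold [%g, %g]: rejected %d of %d pixels",
                lo, hi, n_rejected, int(pmap.valid_mask.sum()))
    if not keep.any():
        warnings.warn("thresholding removed every valid pixel", stacklevel=2)
    return PerfusionMap(f=pmap.f.copy(), valid_mask=keep,
                        lambda_partition=pmap.lambda_partition)


@dataclass
class ROISummary:
    """Per-ROI statistics plus the equal-weight pooled mean."""

    means: list[float]
    sds: list[float]
    n_pixels: list[int]
    pooled_mean: float


def roi_summary(map_obj, rois: list[np.ndarray]) -> ROISummary:
    """Mean/SD of map values over each ROI (valid pixels only).

    ``map_obj`` may be a :class:`PerfusionMap`, a :class:`T1Map` or a
    plain array (all pixels valid).  The pooled mean weights the ROIs
    equally (mean of ROI means), mirroring parenchyma sampling with a
    fixed number of regions.
    """
    if isinstance(map_obj, PerfusionMap):
        values, valid = map_obj.f, map_obj.valid_mask
    elif isinstance(map_obj, T1Map):
        values, valid = map_obj.t1, map_obj.fit_ok
    else:
        values = np.asarray(map_obj, dtype=float)
        valid = np.ones(values.shape, dtype=bool)
    if not rois:
        raise ValueError("need at least one ROI")
    means, sds, ns = [], [], []
    for i, roi in enumerate(rois):
        roi = np.asarray(roi).astype(bool)
        if roi.shape != values.shape:
            raise ValueError(f"ROI {i} shape {roi.shape} != map shape {values.shape}")
        sel = roi & valid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {i} has no valid pixels after thresholding")
        v = values[sel]
        means.append(float(v.mean()))
        sds.append(float(v.std(ddof=1)) if n > 1 else 0.0)
        ns.append(n)
    return ROISummary(means=means, sds=sds, n_pixels=ns,
                      pooled_mean=float(np.mean(means)))


# ---------------------------------------------------------------------------
# I/O: NIfTI / TIFF stacks with a JSON sidecar carrying the TI list
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_ir_series(series: IRSeries, path) -> None:
    """Write an IR stack as NIfTI (.nii) or multi-page TIFF (.tif/.tiff)
    plus a JSON sidecar with the TI list and labeling."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, series.frames.astype(np.float32))
    elif path.suffix == ".nii":
        # TI as 4th dimension: (H, W, 1, n_TI)
        data = np.transpose(series.frames, (1, 2, 0))[:, :, None, :]
        nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), path)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    sidecar = {"inversion_times_ms": series.inversion_times.tolist(),
               "labeling": series.labeling,
               "magnitude_data": series.magnitude_data}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_ir_series(path) -> IRSeries:
    """Read an IR stack written by :func:`save_ir_series`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing TI sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if path.suffix in (".tif", ".tiff"):
        frames = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix == ".nii":
        data = np.asarray(nib.load(path).dataobj, dtype=float)
        frames = np.transpose(data[:, :, 0, :], (2, 0, 1))
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    return IRSeries(inversion_times=np.asarray(meta["inversion_times_ms"]),
                    frames=frames, labeling=meta["labeling"],
                    magnitude_data=bool(meta["magnitude_data"]))


def save_map(values: np.ndarray, path, valid_mask: np.ndarray | None = None) -> None:
    """Write a quantitative map as float32 NIfTI; the validity mask, if
    given, goes to ``<stem>_mask.nii`` as uint8."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), np.eye(4)), path)
    if valid_mask is not None:
        mpath = path.with_name(path.stem + "_mask.nii")
        nib.save(nib.Nifti1Image(valid_mask.astype(np.uint8), np.eye(4)), mpath)


def load_mask(path) -> np.ndarray:
    """Read a boolean ROI mask from NIfTI or TIFF (nonzero = inside)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path)) != 0
    return np.asarray(nib.load(path).dataobj) != 0
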
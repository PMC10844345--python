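"""Per-subject functional-stability computation.

For every cortical vertex, functional connectivity (Pearson r) between that
vertex and a target set (all other masked vertices, or atlas parcel means) is
estimated inside successive sliding windows.  The vertex's *functional
stability* is the Kendall coefficient of concordance W of those windowed FC
maps: windows act as judges ranking the targets, and W in [0, 1] measures how
consistently the vertex's connectivity profile is ordered over time.  High W
means a temporally stable connectivity architecture.

Light preprocessing mirrors standard resting-state practice: dropping initial
volumes, nuisance regression (24-parameter motion model, tissue signals,
linear trend), and a 0.01-0.1 Hz band-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "BoldSeries",
    "WindowSpec",
    "DfcStack",
    "StabilityMap",
    "QCResult",
    "qc_motion",
    "discard_initial",
    "friston24",
    "regress_confounds",
    "bandpass",
    "make_windows",
    "windowed_fc",
    "kendalls_w",
    "stability_map",
    "zscore_map",
]


@dataclass
class BoldSeries:
    """One subject's vertex x timepoint signal matrix with repetition time."""

    data: np.ndarray          # (V, T)
    tr_s: float
    subject_id: str = ""
    hemisphere: str = "single"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (vertices, timepoints)")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def replace(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data, self.tr_s, self.subject_id, self.hemisphere)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds; volumes derived from the TR."""

    window_s: float = 64.0
    step_s: float = 4.0

    def window_vols(self, tr_s: float) -> int:
        return _to_vols(self.window_s, tr_s, "window_s", minimum=3)

    def step_vols(self, tr_s: float) -> int:
        return _to_vols(self.step_s, tr_s, "step_s", minimum=1)


def _to_vols(seconds: float, tr_s: float, name: str, minimum: int) -> int:
    v = seconds / tr_s
    if abs(v - round(v)) > 1e-9:
        raise ValueError(f"{name}={seconds} s is not an integer multiple of TR={tr_s} s")
    v = int(round(v))
    if v < minimum:
        raise ValueError(f"{name} must be at least {minimum} volumes, got {v}")
    return v


@dataclass
class DfcStack:
    """Windowed FC values for one seed vertex: (windows x targets) Pearson r."""

    corr: np.ndarray
    seed_vertex: int
    target_kind: str = "mask-vertices"   # or "parcel-means"


@dataclass
class StabilityMap:
    """Per-vertex Kendall's-W stability values with provenance."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    zscored: bool = False


@dataclass
class QCResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


# ---------------------------------------------------------------------------
# preprocessing

def qc_motion(trace, max_trans_mm: float = 2.5,
              max_rot_deg: float = 2.5) -> QCResult:
    """Exclusion rule: fail iff any |translation| > 2.5 mm or |rotation| > 2.5 deg.

    Boundaries are strict ("exceeding"): a parameter exactly at the limit passes.
    """
    if trace.params.shape[0] == 0:
        raise ValueError("empty motion trace")
    t_max = np.abs(trace.params[:, :3]).max()
    r_max = np.abs(trace.params[:, 3:]).max()
    if t_max > max_trans_mm:
        return QCResult(False, f"max translation {t_max:.3f} mm > {max_trans_mm} mm")
    if r_max > max_rot_deg:
        return QCResult(False, f"max rotation {r_max:.3f} deg > {max_rot_deg} deg")
    return QCResult(True)


def discard_initial(bold: BoldSeries, n_discard: int = 10) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= bold.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_timepoints} volumes")
    return bold.replace(bold.data[:, n_discard:])


def friston24(trace) -> np.ndarray:
    """24-parameter motion regressor table.

    Columns: the 6 rigid-body parameters, their one-volume-lagged copies
    (first row zero-padded), and the squares of both sets.
    """
    p = np.asarray(trace.params, dtype=float)
    if p.shape[0] < 2:
        raise ValueError("motion trace must have at least 2 volumes")
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p ** 2, lag ** 2])


def regress_confounds(bold: BoldSeries, confounds: np.ndarray | None) -> BoldSeries:
    """Per-vertex OLS residualisation against nuisance regressors.

    An intercept is always included; with an empty confound set the result is
    the mean-centred signal.  Residuals are orthogonal to every regressor.
    """
    t = bold.n_timepoints
    x = np.ones((t, 1))
    if confounds is not None and np.size(confounds):
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != t:
            raise ValueError(
                f"confound rows ({c.shape[0]}) must equal timepoints ({t})")
        x = np.hstack([x, c])
    # rank check with column attribution via pivoted QR diagnostics
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [int(i) - 1 for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(
            f"rank-deficient confound design; collinear columns (0-based, "
            f"-1 = intercept): {bad}")
    beta, *_ = np.linalg.lstsq(x, bold.data.T, rcond=None)
    return bold.replace(bold.data - (x @ beta).T)


def bandpass(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldSeries:
    """Frequency-domain band-pass: keep components with low <= f <= high.

    Implemented as an FFT mask; the DC component is always removed when
    ``low_hz > 0``.
    """
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz={high_hz} exceeds Nyquist {nyquist}")
    t = bold.n_timepoints
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    if low_hz > 0:
        keep[0] = False
    spec = np.fft.rfft(bold.data, axis=1)
    spec[:, ~keep] = 0.0
    return bold.replace(np.fft.irfft(spec, n=t, axis=1))


# ---------------------------------------------------------------------------
# windows and windowed FC

def make_windows(n_timepoints: int, tr_s: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Ordered ``[start, stop)`` volume ranges of the sliding windows.

    Count = floor((T - window) / step) + 1; only full windows are used.
    """
    w = spec.window_vols(tr_s)
    s = spec.step_vols(tr_s)
    if w > n_timepoints:
        raise ValueError(
            f"window of {w} volumes longer than series ({n_timepoints})")
    starts = range(0, n_timepoints - w + 1, s)
    return [(a, a + w) for a in starts]


def _window_corr(seed: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson r between one seed series and each target row; NaN when flat."""
    s = seed - seed.mean()
    t = targets - targets.mean(axis=1, keepdims=True)
    sn = np.sqrt(s @ s)
    tn = np.sqrt(np.einsum("ij,ij->i", t, t))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t @ s) / (tn * sn)
    r[~np.isfinite(r)] = np.nan
    return r


def windowed_fc(bold: BoldSeries, seed_vertex: int, targets: np.ndarray,
                windows: list[tuple[int, int]]) -> DfcStack:
    """DFC stack for one seed: Pearson r with each target series per window.

    ``targets`` is either an index array into the BOLD matrix (the seed is
    excluded from its own target set) or a (targets x timepoints) matrix of
    explicit target series.  Zero-variance (flat-window) correlations are
    returned as NaN; :func:`kendalls_w` drops such targets from the ranking.
    """
    targets = np.asarray(targets)
    if targets.ndim == 1:
        idx = targets[targets != seed_vertex]
        series = bold.data[idx]
        kind = "mask-vertices"
    else:
        series = np.asarray(targets, dtype=float)
        kind = "explicit"
    if series.shape[0] < 2:
        raise ValueError("need at least 2 targets")
    rows = []
    for a, b in windows:
        if b - a < 3:
            raise ValueError("windows must contain at least 3 volumes")
        rows.append(_window_corr(bold.data[seed_vertex, a:b], series[:, a:b]))
    return DfcStack(np.array(rows), seed_vertex, kind)


# ---------------------------------------------------------------------------
# Kendall's W

def _w_from_value_matrix(values: np.ndarray) -> float:
    """Tie-corrected Kendall's W of a (judges x items) value matrix.

    Items with any undefined (NaN) value are dropped for all judges, keeping
    the judge/item grid rectangular.  Returns NaN (with a warning) when every
    judge ties all items, which leaves concordance undefined.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 judges and 2 items")
    good = ~np.isnan(m).any(axis=0)
    m = m[:, good]
    if m.shape[1] < 2:
        warnings.warn("fewer than 2 rankable items after dropping undefined "
                      "targets; W undefined", RuntimeWarning)
        return np.nan
    return float(_w_batch(m[None, :, :])[0])


def _w_batch(stacks: np.ndarray) -> np.ndarray:
    """Vectorised tie-corrected W over a (batch, judges, items) array."""
    b, k, n = stacks.shape
    flat = stacks.reshape(b * k, n)
    ranks = rankdata(flat, axis=1).reshape(b, k, n)
    rank_sums = ranks.sum(axis=1)                       # (b, n)
    s = (rank_sums ** 2).sum(axis=1)                    # sum R_i^2
    # per-judge tie correction T = sum over tie groups of (t^3 - t)
    srt = np.sort(flat, axis=1)
    ties = np.zeros(b * k)
    new_group = np.ones((b * k, n), dtype=bool)
    new_group[:, 1:] = srt[:, 1:] != srt[:, :-1]
    group_id = np.cumsum(new_group, axis=1) - 1
    offset = (np.arange(b * k) * n)[:, None]
    counts = np.bincount((group_id + offset).ravel(), minlength=b * k * n)
    ties = np.add.reduceat(counts.astype(float) ** 3 - counts,
                           np.arange(0, b * k * n, n))
    t_sum = ties.reshape(b, k).sum(axis=1)
    num = 12.0 * s - 3.0 * k ** 2 * n * (n + 1) ** 2
    den = k ** 2 * n * (n ** 2 - 1) - k * t_sum
    out = np.full(b, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if np.any(~ok):
        warnings.warn("all items tied in every window for some seeds; "
                      "W undefined there", RuntimeWarning)
    return np.clip(out, 0.0, 1.0, out=out)


def kendalls_w(stack: DfcStack | np.ndarray) -> float:
    """Kendall coefficient of concordance of a windowed-FC stack.

    Windows are judges ranking the connectivity targets; ties receive average
    ranks and the standard tie correction is applied:

        W = (12 * sum R_i^2 - 3 k^2 n (n+1)^2) / (k^2 n (n^2-1) - k * sum T_j)

    with k judges, n items, R_i the rank sum of item i, and T_j the per-judge
    tie term sum(t^3 - t).  The result is clamped to [0, 1] against rounding.
    """
    values = stack.corr if isinstance(stack, DfcStack) else stack
    return _w_from_value_matrix(values)


# ---------------------------------------------------------------------------
# stability maps

def _parcel_target_corr(data: np.ndarray, labels: np.ndarray,
                        parcels: np.ndarray, seed_policy: str) -> np.ndarray:
    """(vertices x parcels) windowed correlations with parcel-mean series.

    For each vertex's own parcel the mean is recomputed without the seed
    vertex (``seed_policy="exclude"``, the default) so a vertex never judges
    a target that contains itself.
    """
    v, t = data.shape
    xc = data - data.mean(axis=1, keepdims=True)
    xn = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    k = len(parcels)
    sums = np.zeros((k, t))
    counts = np.zeros(k)
    for pi, p in enumerate(parcels):
        members = labels == p
        sums[pi] = xc[members].sum(axis=0)
        counts[pi] = members.sum()
    means = sums / counts[:, None]
    mn = np.sqrt(np.einsum("ij,ij->i", means, means))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ means.T) / (xn[:, None] * mn[None, :])
    if seed_policy == "exclude":
        parcel_index = {p: i for i, p in enumerate(parcels)}
        for pi, p in enumerate(parcels):
            members = np.flatnonzero(labels == p)
            npar = len(members)
            if npar < 2:
                r[members, pi] = np.nan       # leave-one-out mean undefined
                continue
            x = xc[members]
            dot_s = x @ sums[pi]              # x_v . S
            x2 = np.einsum("ij,ij->i", x, x)
            loo_num = (dot_s - x2) / (npar - 1)
            loo_nrm = np.sqrt(np.maximum(
                np.einsum("i,i->", sums[pi], sums[pi]) - 2 * dot_s + x2, 0.0)
            ) / (npar - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r[members, pi] = loo_num / (xn[members] * loo_nrm)
    r[~np.isfinite(r)] = np.nan
    return r


def stability_map(bold: BoldSeries, mask: np.ndarray,
                  atlas=None, spec: WindowSpec = WindowSpec(),
                  mode: str = "vertex_by_atlas",
                  seed_policy: str = "exclude") -> StabilityMap:
    """Per-vertex functional-stability (Kendall's W) map.

    ``vertex_by_vertex`` uses every other masked vertex as a connectivity
    target; ``vertex_by_atlas`` uses parcel-mean series (the seed's own
    parcel mean recomputed without the seed when ``seed_policy="exclude"``).
    Unmasked vertices carry NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (bold.n_vertices,):
        raise ValueError("mask length must equal vertex count")
    if mask.sum() < 2:
        raise ValueError("mask must include at least 2 vertices")
    windows = make_windows(bold.n_timepoints, bold.tr_s, spec)
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for a concordance estimate")
    midx = np.flatnonzero(mask)
    vm = len(midx)
    data = bold.data[midx]

    if mode == "vertex_by_vertex":
        stacks = np.empty((len(windows), vm, vm))
        for wi, (a, b) in enumerate(windows):
            seg = data[:, a:b]
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.corrcoef(seg)
            stacks[wi] = c
        # seed i judges all masked vertices but itself
        per_seed = np.empty((vm, len(windows), vm - 1))
        cols = np.arange(vm)
        for i in range(vm):
            per_seed[i] = stacks[:, i, cols != i]
        target_kind = "mask-vertices"
    elif mode == "vertex_by_atlas":
        if atlas is None:
            raise ValueError("vertex_by_atlas mode requires an atlas")
        labels = atlas.labels[midx]
        parcels = np.unique(labels[labels > 0])
        if len(parcels) < 2:
            raise ValueError("vertex_by_atlas mode needs at least 2 parcels")
        per_seed = np.empty((vm, len(windows), len(parcels)))
        for wi, (a, b) in enumerate(windows):
            per_seed[:, wi, :] = _parcel_target_corr(
                data[:, a:b], labels, parcels, seed_policy)
        target_kind = "parcel-means"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    w = np.full(vm, np.nan)
    nan_targets = np.isnan(per_seed).any(axis=1)        # (vm, n_targets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        clean = ~nan_targets.any(axis=1)
        if clean.any():
            w[clean] = _w_batch(per_seed[clean])
        for i in np.flatnonzero(~clean):
            w[i] = _w_from_value_matrix(per_seed[i])

    values = np.full(bold.n_vertices, np.nan)
    values[midx] = w
    prov = {
        "window_s": spec.window_s, "step_s": spec.step_s,
        "n_windows": len(windows), "mode": mode, "target_kind": target_kind,
        "seed_policy": seed_policy, "tr_s": bold.tr_s,
        "subject_id": bold.subject_id,
    }
    return StabilityMap(values, prov)


def zscore_map(smap: StabilityMap, mask: np.ndarray, ddof: int = 1) -> StabilityMap:
    """Standardise a stability map to zero mean / unit SD over the mask.

    Sample (n-1) standard deviation by default; recorded in provenance.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = smap.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite masked values")
    sd = vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot Z-score")
    out = np.array(smap.values, dtype=float)
    out[mask] = (out[mask] - vals.mean()) / sd
    prov = dict(smap.provenance, zscore_ddof=ddof)
    return StabilityMap(out, prov, zscored=True)


def zscore_maps_pooled(maps: list[StabilityMap], masks: list[np.ndarray],
                       ddof: int = 1) -> list[StabilityMap]:
    """Z-score hemisphere maps with mean/SD pooled jointly over all masks."""
    pooled = np.concatenate([
        m.values[np.asarray(k, bool)] for m, k in zip(maps, masks)])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 2:
        raise ValueError("need at least 2 finite masked values")
    sd = pooled.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot Z-score")
    mu = pooled.mean()
    out = []
    for m, k in zip(maps, masks):
        k = np.asarray(k, bool)
        v = np.array(m.values, dtype=float)
        v[k] = (v[k] - mu) / sd
        out.append(StabilityMap(v, dict(m.provenance, zscore_pooled=True), True))
    return out
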
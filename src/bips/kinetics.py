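"""Fluorescence time-series quantification.

Implements the single-molecule analysis chain used for DNA-protein
condensates on doubly tethered DNA: kymograph construction from a movie,
conversion of cluster fluorescence to kilobases of compacted DNA, 5-95%
compaction time on a Savitzky-Golay-smoothed trace, single-exponential fits
for FRAP recovery and dissociation decays, change-point step counting for
photobleaching staircases, and cluster stoichiometry from unit step sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "IntensityTrace",
    "Kymograph",
    "StepTrain",
    "ExpFit",
    "build_kymograph",
    "cluster_size_kbp",
    "compaction_time",
    "fit_exponential",
    "find_steps",
    "count_complexes",
]

LAMBDA_DNA_KBP = 48.5


@dataclass
class IntensityTrace:
    """Background-subtracted intensity versus time."""

    time_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time_s.size > 1 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class Kymograph:
    """Position x time matrix of per-frame-normalised intensity."""

    data: np.ndarray  # (n_positions, n_frames)
    frame_interval_s: float
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class StepTrain:
    """Photobleaching staircase decomposition."""

    step_times: np.ndarray  # seconds
    step_sizes: np.ndarray  # a.u., negative for downward steps
    plateau_levels: np.ndarray  # length = steps + 1
    quality: float = float("nan")  # fit / counter-fit chi-square ratio

    @property
    def n_steps(self) -> int:
        return self.step_times.size


@dataclass
class ExpFit:
    """Single-exponential fit result."""

    tau_s: float
    tau_sd_s: float
    amplitude: float
    baseline: float
    kind: str

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("time constant must be positive")


def build_kymograph(
    image_stack: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    half_width: int = 5,
    frame_interval_s: float = 1.0,
    pixel_size_um: float = 0.1,
    background_kernel: int = 21,
) -> Kymograph:
    """Kymograph from a movie along a line, the standard tethered-DNA recipe.

    Per frame: the intensity is summed over ``2*half_width + 1`` pixels
    perpendicular to the line (11 pixels at the default) at each integer
    position along it; a 2-D median-smoothed background is subtracted first,
    and each frame's profile is normalised by its maximum (zero-max frames
    are left as zeros).
    """
    stack = np.asarray(image_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("image_stack must be (frames, rows, cols)")
    (r0, c0), (r1, c1) = line
    nrow, ncol = stack.shape[1:]
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError("line endpoint outside image")
    length = int(round(np.hypot(r1 - r0, c1 - c0)))
    if length < 2:
        raise ValueError("line is degenerate")
    t = np.linspace(0.0, 1.0, length + 1)
    rr = r0 + t * (r1 - r0)
    cc = c0 + t * (c1 - c0)
    # unit normal to the line
    nr, nc = -(c1 - c0), (r1 - r0)
    norm = np.hypot(nr, nc)
    nr, nc = nr / norm, nc / norm
    offsets = np.arange(-half_width, half_width + 1)
    samp_r = np.clip(
        np.rint(rr[:, None] + offsets[None, :] * nr).astype(int), 0, nrow - 1
    )
    samp_c = np.clip(
        np.rint(cc[:, None] + offsets[None, :] * nc).astype(int), 0, ncol - 1
    )
    profiles = np.empty((length + 1, stack.shape[0]))
    for f in range(stack.shape[0]):
        frame = stack[f]
        bg = median_filter(frame, size=background_kernel, mode="nearest")
        clean = frame - bg
        profiles[:, f] = clean[samp_r, samp_c].sum(axis=1)
        peak = profiles[:, f].max()
        if peak > 0:
            profiles[:, f] /= peak
        else:
            profiles[:, f] = 0.0
    return Kymograph(
        profiles,
        frame_interval_s,
        pixel_size_um,
        meta={"half_width": half_width, "background_kernel": background_kernel},
    )


def cluster_size_kbp(
    roi_trace: IntensityTrace,
    total_trace: IntensityTrace,
    genome_kbp: float = LAMBDA_DNA_KBP,
) -> IntensityTrace:
    """DNA amount in the cluster: (ROI / total DNA intensity) * genome size.

    Both traces must share time stamps and be background-subtracted.  Frames
    with non-positive total are masked (NaN) with a warning.
    """
    if not np.array_equal(roi_trace.time_s, total_trace.time_s):
        raise ValueError("traces are not time-aligned")
    total = total_trace.intensity
    bad = total <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} frames with non-positive total masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        kbp = np.where(bad, np.nan, roi_trace.intensity / total * genome_kbp)
    return IntensityTrace(roi_trace.time_s, kbp)


def compaction_time(
    trace: IntensityTrace,
    savgol_window: int = 250,
    savgol_order: int = 2,
    plateau_drift_tol: float = 0.1,
) -> float:
    """5-95% rise time of a compaction trace, in seconds.

    The trace is Savitzky-Golay smoothed (window shrunk to the largest valid
    odd size when the trace is short), the plateau is the mean of the final
    20% and the baseline the mean of the first 5%; the compaction time runs
    from the first crossing of baseline + 5% of the amplitude to the first
    subsequent crossing of 95%.  Raises when the final plateau still drifts
    by more than ``plateau_drift_tol`` of the amplitude.
    """
    y = trace.intensity.astype(float)
    t = trace.time_s
    n = y.size
    if n < 10:
        raise ValueError("trace too short")
    win = min(savgol_window, n - 1 if (n - 1) % 2 else n - 2)
    win = max(win, savgol_order + 1 + (savgol_order % 2))
    if win % 2 == 0:
        win += 1
    sm = savgol_filter(y, win, savgol_order) if win < n else y.copy()
    tail = sm[int(0.8 * n):]
    base = sm[: max(2, int(0.05 * n))].mean()
    plateau = tail.mean()
    amp = plateau - base
    if amp == 0:
        raise ValueError("flat trace: no compaction detected")
    h1, h2 = tail[: tail.size // 2].mean(), tail[tail.size // 2:].mean()
    if abs(h2 - h1) > plateau_drift_tol * abs(amp):
        raise ValueError("no stable plateau: trace still drifting")
    lo = base + 0.05 * amp
    hi = base + 0.95 * amp
    rising = amp > 0
    above_lo = sm >= lo if rising else sm <= lo
    if not above_lo.any():
        raise ValueError("5% level never crossed")
    i0 = int(np.argmax(above_lo))
    above_hi = sm[i0:] >= hi if rising else sm[i0:] <= hi
    if not above_hi.any():
        raise ValueError("95% level never crossed")
    i1 = i0 + int(np.argmax(above_hi))
    return float(t[i1] - t[i0])


def _exp_model(kind: str):
    if kind == "decay":
        return lambda t, tau, amp, base: base + amp * np.exp(-t / tau)
    if kind == "recovery":
        return lambda t, tau, amp, base: base + amp * (1.0 - np.exp(-t / tau))
    raise ValueError("kind must be 'decay' or 'recovery'")


def fit_exponential(trace: IntensityTrace, kind: str) -> ExpFit:
    """Nonlinear least-squares single-exponential fit.

    decay:    I(t) = baseline + A exp(-t/tau)
    recovery: I(t) = baseline + A (1 - exp(-t/tau))
    tau_sd comes from the fit covariance.  Raises on non-convergence, with
    residual diagnostics in the message.
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 points for an exponential fit")
    t = trace.time_s - trace.time_s[0]
    y = trace.intensity
    model = _exp_model(kind)
    span = float(y.max() - y.min())
    tau0 = max((t[-1] - t[0]) / 3.0, np.finfo(float).tiny)
    if kind == "decay":
        p0 = (tau0, span if span else 1.0, float(y.min()))
    else:
        p0 = (tau0, span if span else 1.0, float(y[0]))
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0,
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = y - model(t, *p0)
        raise RuntimeError(
            f"exponential fit failed: {err}; initial residual rms "
            f"{np.sqrt((resid**2).mean()):.3g}"
        ) from err
    tau, amp, base = popt
    tau_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    if t[-1] < tau:
        warnings.warn(
            f"trace spans {t[-1]:.3g} s < fitted tau {tau:.3g} s; "
            "estimate may be poorly constrained"
        )
    return ExpFit(float(tau), tau_sd, float(amp), float(base), kind)


@njit(cache=True)
def _dp_steps(y, max_steps):
    """Exact DP change-point segmentation minimising within-plateau SSE.

    Returns (cost[k], breaks[k]) for k = 0..max_steps where breaks are the
    last-break backpointers; cost[k][j] is the best SSE of y[:j+1] with k
    steps.
    """
    n = y.size
    c1 = np.zeros(n + 1)
    c2 = np.zeros(n + 1)
    for i in range(n):
        c1[i + 1] = c1[i] + y[i]
        c2[i + 1] = c2[i] + y[i] * y[i]
    # seg_cost(a, b) = SSE of y[a:b]
    cost = np.empty((max_steps + 1, n + 1))
    back = np.zeros((max_steps + 1, n + 1), dtype=np.int64)
    for j in range(n + 1):
        if j == 0:
            cost[0, j] = 0.0
        else:
            s = c1[j] - c1[0]
            q = c2[j] - c2[0]
            cost[0, j] = q - s * s / j
    for k in range(1, max_steps + 1):
        cost[k, : k + 1] = np.inf
        for j in range(k + 1, n + 1):
            best = np.inf
            arg = k
            for i in range(k, j):
                s = c1[j] - c1[i]
                q = c2[j] - c2[i]
                c = cost[k - 1, i] + q - s * s / (j - i)
                if c < best:
                    best = c
                    arg = i
            cost[k, j] = best
            back[k, j] = arg
    return cost, back


def _segment_means(y, breaks):
    edges = [0] + list(breaks) + [y.size]
    return np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def find_steps(
    trace: IntensityTrace,
    max_steps: int | None = None,
    accept_ratio: float = 1.5,
) -> StepTrain:
    """Change-point step detection for photobleaching staircases.

    For each candidate step count k the optimal plateau segmentation
    (minimum within-plateau sum of squares, exact dynamic programme) is
    compared against a counter-fit with the same number of steps placed at
    the midpoints of the fitted plateaus; the accepted k maximises the
    counter-fit/fit chi-square ratio, provided it exceeds ``accept_ratio``
    (otherwise zero steps are reported).  This is the classic step-finding
    scheme for single-fluorophore bleaching.
    """
    y = trace.intensity.astype(float)
    t = trace.time_s
    n = y.size
    if n < 10:
        raise ValueError("trace too short for step finding")
    if max_steps is None:
        max_steps = min(30, n // 4)
    cost, back = _dp_steps(y, max_steps)
    # robust per-point noise variance from first differences (a true step
    # contributes one outlier, which the MAD ignores)
    d = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    sigma2 = max(sigma**2, 1e-30)
    # penalised change-point selection: each extra step must buy more than
    # the expected spurious gain of an optimised break position
    beta = 3.0 * sigma2 * (np.log(n) + 2.0)
    ks = np.arange(max_steps + 1)
    penalised = cost[:, n] + ks * beta
    best_k = int(np.argmin(penalised))
    if best_k == 0:
        return StepTrain(np.empty(0), np.empty(0), np.array([y.mean()]), 0.0)
    breaks = []
    j = n
    for kk in range(best_k, 0, -1):
        j = int(back[kk, j])
        breaks.append(j)
    breaks = sorted(breaks)
    # counter-fit acceptance: the same number of steps placed at plateau
    # midpoints must fit markedly worse than the fitted staircase
    sse_fit = max(cost[best_k, n], 1e-30)
    edges = [0] + breaks + [n]
    counters = sorted(
        {(a + b) // 2 for a, b in zip(edges[:-1], edges[1:]) if b - a >= 2}
    )
    counters = [c for c in counters if 0 < c < n]
    ce = [0] + counters + [n]
    sse_counter = sum(
        ((y[a:b] - y[a:b].mean()) ** 2).sum() for a, b in zip(ce[:-1], ce[1:])
    )
    ratio = sse_counter / sse_fit
    if ratio <= accept_ratio:
        return StepTrain(np.empty(0), np.empty(0), np.array([y.mean()]), ratio)
    levels = _segment_means(y, breaks)
    times = t[np.array(breaks)]
    sizes = np.diff(levels)
    return StepTrain(times, sizes, levels, ratio)


def count_complexes(
    cluster_intensity: float,
    unit_step: float,
    cluster_sd: float | None = None,
    unit_sd: float | None = None,
) -> float | tuple[float, float]:
    """Number of complexes in a cluster: intensity / single-molecule step.

    With both SDs supplied, returns (count, propagated SD).
    """
    if unit_step <= 0:
        raise ValueError("unit step must be positive")
    count = cluster_intensity / unit_step
    if cluster_sd is not None and unit_sd is not None:
        if cluster_intensity == 0:
            return count, 0.0
        sd = abs(count) * np.hypot(
            cluster_sd / cluster_intensity, unit_sd / unit_step
        )
        return count, float(sd)
    return count
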
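"""Nonlinear dynamics features (canonical indices 19-27).

Order: 19 singular spectral entropy, 20 K entropy (correlation entropy K2),
21 approximate entropy, 22 maximum Lyapunov exponent (Rosenstein), 23 C0
complexity, 24 sample entropy, 25 spectral entropy, 26 Lempel-Ziv (LZ76)
complexity, 27 correlation dimension (Grassberger-Procaccia).

Conventions follow the originating methods: Chebyshev (max-norm) distances
and tolerance r expressed as a fraction of the signal sd for ApEn (Pincus,
self-matches included) and SampEn (Richman-Moorman, self-matches excluded);
Euclidean divergence tracking for the Rosenstein Lyapunov estimator;
log-log correlation-integral slopes for D2 and K2.  All nine features are
invariant under amplitude scaling because every tolerance is sd-relative.

Estimators never raise on degenerate (zero-variance) input when called
through :func:`extract_nonlinear`; they return 0 with a flag so batch
extraction of a whole dataset cannot abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "NonlinearParams", "NonlinearFeatureBlock", "approximate_entropy",
    "sample_entropy", "correlation_dimension", "k_entropy", "max_lyapunov",
    "c0_complexity", "singular_spectral_entropy", "spectral_entropy",
    "lz_complexity", "lz76_pattern_count", "extract_nonlinear",
    "autocorr_delay", "embed",
]

#: canonical (index, name) pairs for features 19-27
NONLINEAR_ORDER = (
    "singular_spectral_entropy",
    "k_entropy",
    "approximate_entropy",
    "max_lyapunov",
    "c0_complexity",
    "sample_entropy",
    "spectral_entropy",
    "lz_complexity",
    "correlation_dimension",
)


class NonlinearError(ValueError):
    pass


@dataclass
class NonlinearParams:
    """Estimator settings (the analysis exposes all of them in run config).

    m: embedding dimension for ApEn/SampEn/K2; m_max bounds the dimension
    sweep for the correlation dimension.  r: tolerance as a fraction of the
    signal sd.  tau: embedding delay in samples (None = first zero crossing
    of the autocorrelation, used by Lyapunov/dimension).  ssa_window: lag
    window L of the singular-spectrum trajectory matrix.  c0_ratio: spectral
    mean-power multiple separating the "regular" Fourier part.  gp_points /
    lyap_points cap the number of embedded points used by the O(N^2)
    correlation-integral and divergence searches (longer signals are
    strided), trading a little estimator variance for bounded runtime.
    """

    m: int = 2
    m_max: int = 8
    r: float = 0.2
    tau: int | None = None
    ssa_window: int = 64
    c0_ratio: float = 5.0
    lz_binarize: str = "median"
    gp_points: int = 1000
    lyap_points: int = 1200
    lyap_m: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NonlinearFeatureBlock:
    """Nine named values, canonical indices 19-27."""

    values_by_name: dict
    flags: dict = field(default_factory=dict)

    def values(self) -> np.ndarray:
        return np.array([self.values_by_name[n] for n in NONLINEAR_ORDER])


# ---------------------------------------------------------------------------
# helpers

def embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Delay-embedding matrix, shape (N - (m-1)*tau, m)."""
    x = np.asarray(x, dtype=float)
    n = len(x) - (m - 1) * tau
    if n <= 0:
        raise NonlinearError("series too short for embedding")
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau][:n]


def autocorr_delay(x: np.ndarray, max_lag: int | None = None) -> int:
    """First zero crossing of the autocorrelation (fallback: lag 1)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 1
    max_lag = max_lag or min(len(x) // 4, 256)
    for lag in range(1, max_lag):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0.0:
            return lag
    return max(1, max_lag // 4)


def _template_counts(x: np.ndarray, m: int, r_abs: float, n_templates: int) -> np.ndarray:
    """Per-template count of length-m templates within Chebyshev distance
    r_abs (self included).  Works on 2-d difference matrices accumulated
    over the m offsets, chunked over template rows to bound memory."""
    counts = np.empty(n_templates, dtype=np.int64)
    chunk = max(1, int(2 ** 23 // max(n_templates, 1)))
    for s in range(0, n_templates, chunk):
        e = min(n_templates, s + chunk)
        a = np.abs(x[s:e, None] - x[None, :n_templates])
        for k in range(1, m):
            np.maximum(a, np.abs(x[s + k : e + k, None] - x[None, k : n_templates + k]),
                       out=a)
        counts[s:e] = (a <= r_abs).sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# regularity entropies

def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Pincus ApEn(m, r*sd): Phi_m - Phi_{m+1}, self-matches included."""
    x = np.asarray(x, dtype=float)
    if len(x) < 50:
        raise NonlinearError("need at least 50 samples for ApEn")
    r_abs = r * x.std()
    n = len(x)

    def phi(mm: int) -> float:
        n_templ = n - mm + 1
        c = _template_counts(x, mm, r_abs, n_templ) / n_templ
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


#: sentinel for SampEn when no (m+1)-matches exist: Richman-Moorman upper
#: bound -ln(2 / ((N-m-1)(N-m))) evaluated lazily per call
def _sampen_ceiling(n: int, m: int) -> float:
    return float(np.log((n - m) * (n - m - 1) / 2.0))


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Richman-Moorman SampEn = -ln(A/B), self-matches excluded.

    A = 0 maps to the documented ceiling ln((N-m)(N-m-1)/2); B = 0 (no
    template matches at length m) raises a degeneracy error.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 50:
        raise NonlinearError("need at least 50 samples for SampEn")
    r_abs = r * x.std()
    n_templ = n - m  # same template count at both lengths (Richman-Moorman)
    b = int(_template_counts(x, m, r_abs, n_templ).sum()) - n_templ
    a = int(_template_counts(x, m + 1, r_abs, n_templ).sum()) - n_templ
    if b == 0:
        raise NonlinearError("degenerate SampEn: no length-m template matches")
    if a == 0:
        return _sampen_ceiling(n, m)
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# correlation-integral estimators (Grassberger-Procaccia family)

def _corr_sums(x, m_list, tau, n_r=28, max_points=1000):
    """log-r grid, log C_m(r) curves and the pair count for each m.

    Pairs closer in time than a Theiler window of max(m)*tau samples are
    excluded.  Distances are Chebyshev; the r grid is shared across m so
    inter-m ratios are meaningful, spanning tiny distance quantiles (where
    the fractal scaling lives) up to the median.
    """
    x = np.asarray(x, dtype=float)
    m_big = max(m_list)
    emb_full = embed(x, m_big, tau)
    stride = max(1, int(np.ceil(len(emb_full) / max_points)))
    idx = np.arange(0, len(emb_full), stride)
    theiler = max(m_big * tau, 1)
    ii, jj = np.triu_indices(len(idx), k=1)
    keep = np.abs(idx[ii] - idx[jj]) > theiler
    ii, jj = ii[keep], jj[keep]
    sub = emb_full[idx]
    d_small = np.abs(sub[ii, : min(m_list)] - sub[jj, : min(m_list)]).max(axis=1)
    pos = d_small[d_small > 0]
    if pos.size < 100:
        raise NonlinearError("not enough distinct pair distances")
    # log-spaced *probability* grid: bins concentrate where C(r) changes,
    # so exact recurrences of periodic signals cannot swamp the grid
    probs = np.logspace(np.log10(max(20.0 / pos.size, 1e-5)), np.log10(0.6), n_r)
    r_grid = np.unique(np.quantile(pos, probs))
    r_grid = r_grid[r_grid > 0]
    if len(r_grid) < 5:
        raise NonlinearError("degenerate pair-distance distribution")
    curves = {}
    for m in m_list:
        # distance over the first m coordinates of the same embedded pairs
        d = np.abs(sub[ii, :m] - sub[jj, :m]).max(axis=1)
        c = (d[None, :] <= r_grid[:, None]).mean(axis=1)
        curves[m] = c
    return np.log(r_grid), curves, len(ii)


def _best_window(log_r, log_c, n_pairs, frac=0.5, c_max=0.5, min_pairs=10):
    """Contiguous window spanning `frac` of the usable log-r grid with max
    linear-fit R^2; bins with fewer than min_pairs pairs or C above c_max
    (saturation) are excluded.  Returns (slope, r2, (start, end))."""
    with np.errstate(over="ignore"):
        c = np.exp(log_c)
    valid = np.isfinite(log_c) & (c * n_pairs >= min_pairs) & (c <= c_max)
    # collapse flat steps (exact recurrences of periodic signals produce
    # runs of identical counts that carry no scaling information)
    with np.errstate(invalid="ignore"):
        valid &= np.concatenate([[True], np.diff(log_c) != 0.0])
    lr, lc = log_r[valid], log_c[valid]
    npts = len(lr)
    if npts < 5:
        raise NonlinearError("no usable scaling region")
    w = max(4, int(np.ceil(npts * frac)))
    best = (np.nan, -np.inf, (0, 0))
    orig_idx = np.flatnonzero(valid)
    for s in range(0, npts - w + 1):
        xs, ys = lr[s : s + w], lc[s : s + w]
        if ys.max() - ys.min() < 0.5:  # not a real scaling window
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        ss_tot = np.sum((ys - ys.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
        if r2 > best[1]:
            best = (slope, r2, (int(orig_idx[s]), int(orig_idx[s + w - 1]) + 1))
    if not np.isfinite(best[0]):
        raise NonlinearError("no usable scaling region")
    return best


def correlation_dimension(
    x: np.ndarray,
    m_range: tuple[int, int] = (2, 8),
    tau: int | None = None,
    max_points: int = 1000,
    return_details: bool = False,
):
    """Grassberger-Procaccia D2: slope of log C(r) vs log r over the best
    scaling window, at the embedding dimension where the slope saturates
    (change < 0.1 between successive m).  Stochastic series never saturate
    and are flagged."""
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise NonlinearError("need at least 500 samples for D2")
    if tau is None:
        tau = autocorr_delay(x)
    m_list = list(range(m_range[0], m_range[1] + 1))
    log_r, curves, n_pairs = _corr_sums(x, m_list, tau, max_points=max_points)
    slopes, r2s = [], []
    for m in m_list:
        with np.errstate(divide="ignore"):
            log_c = np.log(curves[m])
        slope, r2, _ = _best_window(log_r, log_c, n_pairs)
        slopes.append(slope)
        r2s.append(r2)
    saturated = None
    for i in range(1, len(slopes)):
        if abs(slopes[i] - slopes[i - 1]) < 0.1:
            saturated = i
            break
    flags = {}
    if saturated is None:
        saturated = len(slopes) - 1
        flags["no_saturation"] = True
    if r2s[saturated] < 0.95:
        flags["low_confidence"] = True
    d2 = float(slopes[saturated])
    if return_details:
        return d2, {"slopes": slopes, "r2": r2s, "m": m_list, "flags": flags, "tau": tau}
    return d2


def k_entropy(
    x: np.ndarray,
    m: int = 2,
    m_hi: int = 7,
    tau: int | None = None,
    max_points: int = 1000,
    return_details: bool = False,
):
    """Correlation entropy K2 in nats per sample step.

    Grassberger-Procaccia: in the scaling region C_m(r) ~ r^D2 exp(-m tau
    K2), so K2 is estimated as minus the slope of ln C_m(r) against m
    (averaged over the usable r bins) divided by tau.  ~0 for periodic
    dynamics, positive for chaos, a lower bound on the KS entropy.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise NonlinearError("need at least 500 samples for K2")
    if tau is None:
        tau = autocorr_delay(x)
    m_list = list(range(m, m_hi + 1))
    log_r, curves, n_pairs = _corr_sums(x, m_list, tau, max_points=max_points)
    c = np.array([curves[mm] for mm in m_list])  # (n_m, n_r)
    # r bins usable across every m: enough pairs at the largest m, below
    # saturation at the smallest m
    valid = (c[-1] * n_pairs >= 10) & (c[0] <= 0.5)
    if valid.sum() < 3:
        raise NonlinearError("no usable scaling region for K2")
    with np.errstate(divide="ignore"):
        log_c = np.log(c[:, valid])
    slopes = np.polyfit(np.array(m_list, dtype=float), log_c, 1)[0]
    k2 = float(max(0.0, -np.mean(slopes)) / tau)
    if return_details:
        return k2, {"n_bins": int(valid.sum()), "tau": tau, "per_bin": -slopes / tau}
    return k2


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein small-data method)

def _mean_period(x: np.ndarray) -> int:
    """Reciprocal of the mean power-weighted frequency, in samples."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x))
    p[0] = 0.0
    tot = p.sum()
    if tot == 0:
        return 1
    mean_f = float((f * p).sum() / tot)
    return max(1, int(round(1.0 / mean_f))) if mean_f > 0 else 1


def max_lyapunov(
    x: np.ndarray,
    m: int = 5,
    tau: int | None = None,
    max_points: int = 1200,
    k_max: int = 40,
    return_details: bool = False,
):
    """Rosenstein estimate of the largest Lyapunov exponent (nats/step).

    Each embedded point is paired with its nearest neighbour at least a
    Theiler window (max of mean period and m*tau) away in time; the slope of
    the mean log divergence over the initial linear region is the estimate.
    The initial region ends where the curve comes within 1 nat of its
    saturation level.  A flag marks series with no deterministic divergence
    region (the curve jumps to saturation immediately, as for white noise).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise NonlinearError("need at least 500 samples for the Lyapunov exponent")
    if tau is None:
        tau = autocorr_delay(x)
    emb_all = embed(x, m, tau)
    stride = max(1, int(np.ceil(len(emb_all) / max_points)))
    emb = emb_all[::stride]
    n_pts = len(emb)
    theiler = max(_mean_period(x) // stride, (m * tau) // stride, 1)
    k_max = min(k_max, n_pts // 4)
    if k_max < 3:
        raise NonlinearError("series too short for divergence tracking")
    # nearest neighbour outside the Theiler window (accumulated squared
    # distances keep the working set 2-d)
    d = np.zeros((n_pts, n_pts))
    for k in range(m):
        diff = emb[:, k, None] - emb[None, :, k]
        d += diff * diff
    np.sqrt(d, out=d)
    i_idx = np.arange(n_pts)
    band = np.abs(i_idx[:, None] - i_idx[None, :]) <= theiler
    d[band] = np.inf
    nn = np.argmin(d, axis=1)
    valid = np.isfinite(d[i_idx, nn])
    pairs = [(i, nn[i]) for i in i_idx[valid] if max(i, nn[i]) + k_max < n_pts]
    if len(pairs) < 10:
        raise NonlinearError("fewer than 10 valid neighbour pairs")
    pairs = np.array(pairs)
    ii, jj = pairs[:, 0], pairs[:, 1]
    y = np.empty(k_max + 1)
    for k in range(k_max + 1):
        dk = np.linalg.norm(emb[ii + k] - emb[jj + k], axis=1)
        dk = dk[dk > 0]
        y[k] = np.mean(np.log(dk)) if dk.size else -np.inf
    y_sat = np.mean(y[-max(3, k_max // 4):])
    flags = {}
    above = np.nonzero(y >= y_sat - 1.0)[0]
    k_lin = int(above[0]) if above.size else k_max
    if k_lin <= 1:
        flags["no_divergence_region"] = True
        k_lin = max(k_lin, 3)
    k_lin = max(k_lin, 2)
    steps = np.arange(k_lin + 1) * stride
    slope = float(np.polyfit(steps, y[: k_lin + 1], 1)[0])
    if return_details:
        return slope, {"curve": y, "k_lin": k_lin, "flags": flags, "tau": tau,
                       "stride": stride, "n_pairs": len(pairs)}
    return slope


# ---------------------------------------------------------------------------
# spectral decomposition complexities

def c0_complexity(x: np.ndarray, c0_ratio: float = 5.0) -> float:
    """Fraction of signal energy outside the dominant Fourier components.

    Coefficients with |F(k)|^2 > c0_ratio * mean|F|^2 form the "regular"
    part; C0 is the energy of the residual (irregular) part divided by the
    total energy.  Regular signals -> ~0, broadband noise -> ~1.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise NonlinearError("need at least 64 samples for C0")
    energy = float(np.sum(x ** 2))
    if energy == 0.0:
        raise NonlinearError("degenerate C0: zero-energy input")
    F = np.fft.fft(x)
    power = np.abs(F) ** 2
    g = power.mean()
    regular = np.where(power > c0_ratio * g, F, 0.0)
    residual = x - np.real(np.fft.ifft(regular))
    return float(np.sum(residual ** 2) / energy)


def singular_spectral_entropy(x: np.ndarray, window: int = 64) -> float:
    """Normalized Shannon entropy of the singular-value spectrum of the
    L-lag trajectory matrix; in [0, 1] (0 = rank-1, 1 = flat spectrum)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * window:
        raise NonlinearError("series shorter than twice the SSA window")
    traj = embed(x, window)
    gram = traj.T @ traj
    eig = np.linalg.eigvalsh(gram)
    sv = np.sqrt(np.clip(eig, 0.0, None))
    total = sv.sum()
    if total == 0.0:
        raise NonlinearError("degenerate singular spectrum: zero signal")
    p = sv / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(window))


def spectral_entropy(x: np.ndarray) -> float:
    """Normalized Shannon entropy of the one-sided power spectrum in [0, 1]
    (mean removed first so the value reflects oscillatory structure)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise NonlinearError("need at least 64 samples for spectral entropy")
    x = x - x.mean()
    p = np.abs(np.fft.rfft(x)) ** 2
    p = p[1:]  # DC removed with the mean
    total = p.sum()
    if total == 0.0:
        raise NonlinearError("degenerate spectral entropy: zero-energy input")
    q = p / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(len(p)))


# ---------------------------------------------------------------------------
# Lempel-Ziv (1976) complexity

def lz76_pattern_count(bits) -> int:
    """Number of distinct patterns in the LZ76 exhaustive-history parsing.

    Kaspar-Schuster scan: the history s[0:l] is searched for the longest
    reproducible prefix of the remainder; each failure to reproduce closes a
    word and increments the count.
    """
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        raise NonlinearError("empty sequence")
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def lz_complexity(x: np.ndarray, binarize: str = "median", return_details: bool = False):
    """Normalized LZ76 complexity c(n) * log2(n) / n of the binarized series.

    Default binarization: 1 where the sample exceeds the median.  For a
    random binary sequence the value tends to ~1; regular sequences are
    far below.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 64:
        raise NonlinearError("need at least 64 samples for LZ complexity")
    if binarize == "median":
        bits = x > np.median(x)
    elif binarize == "mean":
        bits = x > np.mean(x)
    else:
        raise NonlinearError(f"unknown binarization rule {binarize!r}")
    flags = {}
    if bits.all() or not bits.any():
        flags["constant_binarization"] = True
    c = lz76_pattern_count(bits)
    val = float(c * np.log2(n) / n)
    if return_details:
        return val, {"pattern_count": c, "flags": flags}
    return val


# ---------------------------------------------------------------------------
# batch extraction

def extract_nonlinear(epoch: np.ndarray, params: NonlinearParams | None = None) -> NonlinearFeatureBlock:
    """All nine nonlinear features of one single-channel epoch, in canonical
    order, with per-feature degeneracy flags instead of exceptions."""
    params = params or NonlinearParams()
    x = np.asarray(epoch, dtype=float)
    flags: dict = {}
    if x.std() == 0.0:
        return NonlinearFeatureBlock(
            values_by_name={name: 0.0 for name in NONLINEAR_ORDER},
            flags={name: "degenerate: constant input" for name in NONLINEAR_ORDER},
        )
    tau_dyn = params.tau if params.tau is not None else autocorr_delay(x)
    vals: dict = {}

    def _safe(name, fn):
        try:
            vals[name] = float(fn())
        except NonlinearError as exc:
            vals[name] = 0.0
            flags[name] = str(exc)

    _safe("singular_spectral_entropy", lambda: singular_spectral_entropy(x, params.ssa_window))
    _safe("k_entropy", lambda: k_entropy(x, params.m, tau=tau_dyn, max_points=params.gp_points))
    _safe("approximate_entropy", lambda: approximate_entropy(x, params.m, params.r))
    _safe("max_lyapunov", lambda: max_lyapunov(
        x, m=params.lyap_m, tau=tau_dyn, max_points=params.lyap_points))
    _safe("c0_complexity", lambda: c0_complexity(x, params.c0_ratio))
    _safe("sample_entropy", lambda: sample_entropy(x, params.m, params.r))
    _safe("spectral_entropy", lambda: spectral_entropy(x))
    _safe("lz_complexity", lambda: lz_complexity(x, params.lz_binarize))
    _safe("correlation_dimension", lambda: correlation_dimension(
        x, (params.m, params.m_max), tau=tau_dyn, max_points=params.gp_points))
    return NonlinearFeatureBlock(values_by_name=vals, flags=flags)
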
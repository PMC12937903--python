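"""Phase-space reconstruction and nonlinear invariants.

Implements delay estimation from the non-centered autocorrelation,
Takens delay embedding, false-nearest-neighbor (FNN) selection of the
embedding dimension, the Grassberger-Procaccia correlation dimension,
a Wolf-style largest Lyapunov exponent, and surrogate-data testing of
nonlinearity.

Conventions
-----------
* The autocorrelation is the non-centered estimator
  ``R(j) = (1/n) * sum_i x(i) x(i+j)`` with fixed divisor ``n`` (no mean
  subtraction); a ``centered`` flag enables the more common centered
  variant.  The delay is the first lag where ``R`` falls below
  ``(1 - e^{-1}) R(0)``.
* Distances are Euclidean; nearest-neighbor ties resolve to the
  smallest index.
* The correlation integral counts ordered pairs ``j != k`` and is
  normalized by ``N^2``; a Theiler window is available but off by
  default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy.spatial import cKDTree

from .synthetic import TimeSeries

__all__ = [
    "DelayNotFoundError",
    "EmbeddingParams",
    "EmbeddedTrajectory",
    "FNNResult",
    "CorrelationCurve",
    "ChaosMetrics",
    "SurrogateResult",
    "autocorrelation",
    "estimate_delay",
    "embed",
    "estimate_embedding_dim",
    "correlation_dimension",
    "lyapunov_wolf",
    "phase_randomized_surrogate",
    "surrogate_test",
    "chaos_report",
]


class DelayNotFoundError(ValueError):
    """Raised when the autocorrelation never crosses the delay threshold."""

    def __init__(self, message: str, last_value: float):
        super().__init__(message)
        self.last_value = float(last_value)


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: delay ``tau`` (samples), dimension
    ``m`` and the FNN distance-ratio threshold ``r0`` (dimensionless)."""

    tau: int
    m: int
    r0: float = 15.0

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError("tau must be an integer >= 1")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("m must be an integer >= 1")
        if not self.r0 > 0:
            raise ValueError("r0 must be positive")


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """N x m matrix of delay vectors with (m, tau) provenance.

    Satisfies ``N = source_length - (m - 1) * tau`` exactly.
    """

    points: np.ndarray
    tau: int
    m: int
    source_length: int

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        if points.ndim != 2:
            raise ValueError("points must be a 2-D array")
        n_expected = self.source_length - (self.m - 1) * self.tau
        if points.shape != (n_expected, self.m):
            raise ValueError(
                f"expected {n_expected} x {self.m} points for source_length="
                f"{self.source_length}, got {points.shape}"
            )
        if n_expected < 1:
            raise ValueError("embedding would contain no points")
        object.__setattr__(self, "points", points)

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def from_points(cls, points: np.ndarray, tau: int = 1) -> "EmbeddedTrajectory":
        """Wrap an arbitrary point cloud (e.g. iid samples) as a trajectory."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n, m = points.shape
        return cls(points=points, tau=tau, m=m, source_length=n + (m - 1) * tau)


@dataclass(frozen=True)
class FNNResult:
    """FNN embedding-dimension selection outcome.

    ``fractions[i]`` is the false-neighbor fraction at dimension
    ``i + 1``; ``converged`` is False when no dimension satisfied the
    stopping criterion and ``m`` fell back to ``m_max``.
    """

    m: int
    fractions: np.ndarray
    converged: bool

    def __iter__(self):  # allow ``m, curve = estimate_embedding_dim(...)``
        return iter((self.m, self.fractions))


@dataclass(frozen=True)
class CorrelationCurve:
    """Correlation integral C(r) on log-spaced radii with its scaling fit."""

    radii: np.ndarray
    c_values: np.ndarray
    fit_lo: float
    fit_hi: float
    slope: float

    @property
    def d2(self) -> float:
        return self.slope


@dataclass(frozen=True)
class ChaosMetrics:
    """Per-signal nonlinear invariants.

    ``lambda1`` is in inverse samples for maps and inverse time units
    for flows (see ``lambda1_units``).
    """

    tau: int
    m: int
    d2: float
    lambda1: float
    lambda1_units: str = "1/sample"
    surrogate_p: float | None = None

    def __post_init__(self) -> None:
        if self.d2 < 0:
            raise ValueError("d2 must be non-negative")
        if self.surrogate_p is not None and not 0 < self.surrogate_p <= 1:
            raise ValueError("surrogate_p must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "tau": self.tau, "m": self.m, "d2": self.d2,
            "lambda1": self.lambda1, "lambda1_units": self.lambda1_units,
            "surrogate_p": self.surrogate_p,
        }


@dataclass(frozen=True)
class SurrogateResult:
    """Rank test of a nonlinear statistic against phase-randomized surrogates."""

    statistic_name: str
    original_value: float
    surrogate_values: np.ndarray
    rank_p: float
    sided: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "surrogate_values",
                           np.asarray(self.surrogate_values, dtype=float))


# ---------------------------------------------------------------------------
# delay estimation
# ---------------------------------------------------------------------------

def autocorrelation(x: np.ndarray, max_lag: int, centered: bool = False) -> np.ndarray:
    """Autocorrelation R(0..max_lag) with fixed divisor n.

    Non-centered by default: ``R(j) = (1/n) sum_{i} x(i) x(i+j)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if centered:
        x = x - x.mean()
    return np.array([np.dot(x[: n - j], x[j:]) / n for j in range(max_lag + 1)])


def estimate_delay(series: TimeSeries, max_lag: int, centered: bool = False) -> int:
    """Smallest lag where the autocorrelation falls below (1 - 1/e) R(0).

    Raises
    ------
    DelayNotFoundError
        If no lag up to ``max_lag`` crosses the threshold (e.g. a
        constant series); the exception carries the last R value.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(series) <= max_lag:
        raise ValueError("series must be longer than max_lag")
    r = autocorrelation(series.values, max_lag, centered=centered)
    if r[0] == 0:
        raise DelayNotFoundError("delay not found: zero-energy series", r[-1])
    threshold = (1.0 - np.exp(-1.0)) * r[0]
    below = np.nonzero(r[1:] < threshold)[0]
    if below.size == 0:
        raise DelayNotFoundError(
            f"delay not found within max_lag={max_lag} (last R={r[-1]:.6g}, "
            f"threshold={threshold:.6g})",
            r[-1],
        )
    return int(below[0] + 1)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def embed(series: TimeSeries | np.ndarray, params: EmbeddingParams) -> EmbeddedTrajectory:
    """Takens delay embedding: row i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    n = x.size
    tau, m = params.tau, params.m
    n_points = n - (m - 1) * tau
    if n_points < 1:
        raise ValueError(
            f"series too short: n={n} allows no {m}-dimensional embedding at tau={tau}"
        )
    points = np.column_stack([x[j * tau: j * tau + n_points] for j in range(m)])
    return EmbeddedTrajectory(points=points, tau=tau, m=m, source_length=n)


# ---------------------------------------------------------------------------
# false nearest neighbors
# ---------------------------------------------------------------------------

def _nearest_neighbors(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index and distance of each point's nearest neighbor (self excluded)."""
    tree = cKDTree(points)
    dists, idx = tree.query(points, k=2)
    neighbor = idx[:, 1].astype(int)
    dist = dists[:, 1]
    # query puts the self-match first except under exact duplicates
    self_first = idx[:, 0] != np.arange(points.shape[0])
    neighbor[self_first] = idx[self_first, 0]
    dist[self_first] = dists[self_first, 0]
    return neighbor, dist


def estimate_embedding_dim(
    series: TimeSeries,
    tau: int,
    r0: float = 15.0,
    m_max: int = 10,
    fnn_stop: float = 0.01,
    a_tol: float | None = 2.0,
) -> FNNResult:
    """Select the embedding dimension by the false-nearest-neighbor method.

    For each ``m`` the nearest neighbor of every delay vector is found in
    m dimensions and the squared-distance growth ratio
    ``R(i) = (R_{m+1}(i)^2 - R_m(i)^2) / R_m(i)^2`` is computed; the
    neighbor is false when ``R(i) > r0``.  A second criterion flags the
    neighbor as false when the (m+1)-dimensional separation exceeds
    ``a_tol`` times the series' standard deviation — without it, iid
    noise can masquerade as a low-dimensional signal; pass
    ``a_tol=None`` to use the distance-ratio criterion alone.

    Returns the smallest ``m`` whose false fraction drops below
    ``fnn_stop`` or whose fraction stops decreasing after having fallen
    below 10%; otherwise ``m_max`` with ``converged=False``.
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    x = series.values
    n = x.size
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate series: all samples identical")

    fractions: list[float] = []
    for m in range(1, m_max + 1):
        n_pts = n - m * tau  # points extendable to dimension m+1
        if n_pts < 10:
            raise ValueError(
                f"series too short to evaluate FNN at m_max={m_max} (tau={tau})"
            )
        pts = np.column_stack([x[j * tau: j * tau + n_pts] for j in range(m)])
        neighbor, dist = _nearest_neighbors(pts)
        extra = np.abs(x[m * tau: m * tau + n_pts]
                       - x[neighbor + m * tau])
        # exact recurrences (e.g. perfectly periodic series) produce
        # distances at rounding-error scale whose ratio is meaningless
        floor = 1e-9 * sd
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_sq = (extra / dist) ** 2
        false = np.where(dist > floor, ratio_sq > r0, extra > floor)
        if a_tol is not None:
            dist_next = np.sqrt(dist**2 + extra**2)
            false |= dist_next / sd > a_tol
        fractions.append(float(false.mean()))

        if fractions[-1] < fnn_stop:
            return FNNResult(m=m, fractions=np.array(fractions), converged=True)
        if m >= 2 and fractions[-1] >= fractions[-2] and fractions[-2] < 0.10:
            return FNNResult(m=m - 1, fractions=np.array(fractions), converged=True)

    warnings.warn(
        "FNN fraction did not satisfy the stopping criterion; returning m_max",
        RuntimeWarning,
        stacklevel=2,
    )
    return FNNResult(m=m_max, fractions=np.array(fractions), converged=False)


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def _subsample_distances(points: np.ndarray, max_points: int = 1500) -> np.ndarray:
    """Pairwise distances of an evenly strided subsample (for quantiles)."""
    from scipy.spatial.distance import pdist

    n = points.shape[0]
    if n > max_points:
        idx = np.linspace(0, n - 1, max_points).astype(int)
        points = points[idx]
    return pdist(points)


def _pair_counts(points: np.ndarray, radii: np.ndarray, theiler: int) -> np.ndarray:
    """Number of unordered pairs (|j - k| > theiler) within each radius."""
    n = points.shape[0]
    sq_edges = np.concatenate([radii**2, [np.inf]])
    hist = np.zeros(radii.size + 1, dtype=np.int64)
    chunk = max(8, int(4e6 // max(n, 1)))
    cols = np.arange(n)
    for start in range(0, n, chunk):
        block = points[start:start + chunk]
        d2 = ((block[:, None, :] - points[None, :, :]) ** 2).sum(axis=-1)
        rows = np.arange(start, start + block.shape[0])
        mask = cols[None, :] > (rows[:, None] + theiler)
        hist += np.histogram(d2[mask], bins=np.concatenate([[0.0], sq_edges]))[0]
    return np.cumsum(hist)[: radii.size]


def correlation_dimension(
    traj: EmbeddedTrajectory,
    n_radii: int = 40,
    fit_quantiles: tuple[float, float] = (0.002, 0.02),
    fit_bounds: tuple[float, float] | None = None,
    theiler: int = 0,
) -> CorrelationCurve:
    """Grassberger-Procaccia correlation integral and dimension estimate.

    ``C(r) = (1/N^2) sum_{j != k} H(r - ||X_j - X_k||)`` is evaluated on
    log-spaced radii; D2 is the least-squares slope of ln C vs ln r over
    the scaling region.  The region defaults to radii between the 0.2nd
    and 2nd percentiles of the nonzero pairwise distances
    (``fit_quantiles``) — on smooth attractors the log-log curve is only
    linear at radii that are a small fraction of the attractor diameter,
    and the local slope decays toward saturation well before the median
    distance.  Explicit radius bounds override via ``fit_bounds``.
    ``theiler > 0`` additionally excludes temporally close pairs
    ``|j - k| <= theiler`` (default 0: exactly the ``j != k`` sum).
    """
    points = traj.points
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if n < 100:
        warnings.warn("fewer than 100 points: D2 estimate will be unreliable",
                      RuntimeWarning, stacklevel=2)
    sample = _subsample_distances(points)
    nonzero = sample[sample > 0]
    if nonzero.size == 0:
        raise ValueError("all pairwise distances are zero")

    r_lo = max(np.quantile(nonzero, 0.001), nonzero.min())
    r_hi = nonzero.max() * 1.05
    radii = np.geomspace(r_lo, r_hi, n_radii)
    counts = _pair_counts(points, radii, theiler)
    c_values = 2.0 * counts / float(n) ** 2

    if fit_bounds is not None:
        fit_lo, fit_hi = map(float, fit_bounds)
    else:
        q_lo, q_hi = fit_quantiles
        if not 0 <= q_lo < q_hi <= 1:
            raise ValueError("fit_quantiles must satisfy 0 <= lo < hi <= 1")
        fit_lo = float(np.quantile(nonzero, q_lo))
        fit_hi = float(np.quantile(nonzero, q_hi))
    in_fit = (radii >= fit_lo) & (radii <= fit_hi) & (c_values > 0)
    if in_fit.sum() < 3:
        raise ValueError("fit range contains fewer than 3 radii with C(r) > 0")
    slope = float(np.polyfit(np.log(radii[in_fit]), np.log(c_values[in_fit]), 1)[0])
    return CorrelationCurve(radii=radii, c_values=c_values,
                            fit_lo=fit_lo, fit_hi=fit_hi, slope=slope)


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Wolf-style trajectory tracking)
# ---------------------------------------------------------------------------

def lyapunov_wolf(
    traj: EmbeddedTrajectory,
    dt: float,
    evolve_steps: int = 3,
    min_sep: float | None = None,
    max_sep: float | None = None,
    theiler: int | None = None,
    n_candidates: int = 64,
) -> float:
    """Largest Lyapunov exponent by Wolf-style neighbor tracking.

    Starting from the first point, the nearest neighbor outside the
    Theiler window is tracked for ``evolve_steps`` samples and the log
    of the separation growth accumulated.  When the separation exceeds
    ``max_sep`` the neighbor is replaced by a near point that minimizes
    the change in orientation of the separation vector (preferring
    separations above the ``min_sep`` noise floor, ties to the smallest
    index); candidates come from the ``n_candidates`` nearest neighbors
    of the fiducial point.  The exponent is the accumulated sum divided
    by the total evolved time; positive values flag chaotic divergence.

    Defaults keep the measurement inside the linearization regime:
    ``theiler = tau``, ``min_sep`` = 0.5th percentile of the pairwise
    distances (a noise floor of a fraction of a percent of the attractor
    size), ``max_sep = 10 * min_sep``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if evolve_steps < 1:
        raise ValueError("evolve_steps must be >= 1")
    points = traj.points
    n = points.shape[0]
    if n < 2 * evolve_steps + 2:
        raise ValueError("trajectory too short for the requested evolution")
    theiler = traj.tau if theiler is None else int(theiler)

    tree = cKDTree(points)
    if min_sep is None:
        sample = _subsample_distances(points)
        positive = sample[sample > 0]
        if positive.size == 0:
            raise ValueError("all points coincide; no admissible neighbors")
        min_sep = float(np.quantile(positive, 0.005))
    if max_sep is None:
        max_sep = 10.0 * min_sep

    def candidates(i: int) -> tuple[np.ndarray, np.ndarray]:
        k = min(n, max(n_candidates, 2 * (theiler + evolve_steps) + 8))
        dists, idx = tree.query(points[i], k=k)
        dists = np.atleast_1d(dists)
        idx = np.atleast_1d(idx).astype(int)
        keep = (dists > 0) & (np.abs(idx - i) > theiler) & (idx + evolve_steps < n)
        return idx[keep], dists[keep]

    def initial_neighbor(i: int) -> int | None:
        idx, _ = candidates(i)
        return int(idx[0]) if idx.size else None

    def replacement(i: int, direction: np.ndarray) -> int | None:
        idx, dists = candidates(i)
        if idx.size == 0:
            return None
        within = dists <= max_sep
        if within.any():
            idx, dists = idx[within], dists[within]
        vecs = points[idx] - points[i]
        norm_dir = np.linalg.norm(direction)
        if norm_dir > 0:
            angles = np.arccos(np.clip(vecs @ direction / (dists * norm_dir), -1, 1))
        else:
            angles = np.zeros(dists.size)
        order = np.lexsort((idx, dists, angles, dists < min_sep))
        return int(idx[order[0]])

    i = 0
    j = initial_neighbor(i)
    if j is None:
        raise ValueError("no admissible neighbors found")
    log_sum = 0.0
    steps = 0
    while i + evolve_steps < n and j + evolve_steps < n:
        d0 = np.linalg.norm(points[i] - points[j])
        i2, j2 = i + evolve_steps, j + evolve_steps
        d1 = np.linalg.norm(points[i2] - points[j2])
        if d0 > 0 and d1 > 0:
            log_sum += np.log(d1 / d0)
            steps += evolve_steps
        i = i2
        if i + evolve_steps >= n:
            break
        if d1 > max_sep or abs(j2 - i) <= theiler or j2 + evolve_steps >= n or d1 == 0:
            direction = points[j2] - points[i] if d1 > 0 else np.zeros(traj.m)
            new_j = replacement(i, direction)
            if new_j is None:
                new_j = initial_neighbor(i)
            if new_j is None:
                break
            j = new_j
        else:
            j = j2
    if steps == 0:
        raise ValueError("no admissible neighbor evolutions; cannot estimate lambda1")
    return log_sum / (steps * dt)


# ---------------------------------------------------------------------------
# surrogate-data testing
# ---------------------------------------------------------------------------

def phase_randomized_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier-amplitude-preserving surrogate with randomized phases."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spectrum = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2 * np.pi, spectrum.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spectrum) * np.exp(1j * phases), n)


def _statistic_value(
    x: np.ndarray,
    sampling_rate: float,
    statistic: str,
    tau: int,
    m: int,
    **kwargs,
) -> float:
    traj = embed(TimeSeries(x, sampling_rate), EmbeddingParams(tau=tau, m=m))
    if statistic == "lambda1":
        return lyapunov_wolf(traj, dt=1.0 / sampling_rate, **kwargs)
    if statistic == "D2":
        return correlation_dimension(traj, **kwargs).slope
    raise ValueError(f"unknown statistic {statistic!r}")


def surrogate_test(
    series: TimeSeries,
    statistic: Literal["lambda1", "D2"] = "lambda1",
    n_surrogates: int = 19,
    sided: Literal["greater", "less"] = "greater",
    seed: int = 0,
    tau: int | None = None,
    m: int | None = None,
    **stat_kwargs,
) -> SurrogateResult:
    """Rank test of a nonlinear statistic against phase-randomized surrogates.

    The embedding parameters are estimated once on the original series
    (unless given) and reused for every surrogate, so the test isolates
    the statistic itself.  The rank p-value is
    ``(1 + #{surrogates at least as extreme}) / (B + 1)``.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if len(series) < 128:
        raise ValueError("series must contain at least 128 samples")
    if sided not in ("greater", "less"):
        raise ValueError("sided must be 'greater' or 'less'")

    if tau is None:
        tau = estimate_delay(series, max_lag=max(1, len(series) // 4))
    if m is None:
        m = estimate_embedding_dim(series, tau=tau).m

    original = _statistic_value(series.values, series.sampling_rate,
                                statistic, tau, m, **stat_kwargs)
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_surrogates):
        surrogate = phase_randomized_surrogate(series.values, rng)
        try:
            values.append(_statistic_value(surrogate, series.sampling_rate,
                                           statistic, tau, m, **stat_kwargs))
        except ValueError:
            failures += 1
    if failures > 0.2 * n_surrogates:
        raise ValueError(
            f"statistic failed on {failures}/{n_surrogates} surrogates"
        )
    values_arr = np.array(values)
    if sided == "greater":
        extreme = int(np.sum(values_arr >= original))
    else:
        extreme = int(np.sum(values_arr <= original))
    rank_p = (1 + extreme) / (values_arr.size + 1)
    return SurrogateResult(statistic_name=statistic, original_value=original,
                           surrogate_values=values_arr, rank_p=rank_p, sided=sided)


# ---------------------------------------------------------------------------
# convenience report
# ---------------------------------------------------------------------------

def chaos_report(
    series: TimeSeries,
    max_lag: int | None = None,
    m_max: int = 10,
    r0: float = 15.0,
    run_surrogates: bool = False,
    n_surrogates: int = 19,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> dict:
    """Estimate (tau, m, D2, lambda1) for one signal and optionally test
    nonlinearity against surrogates; returns (and optionally writes) a
    JSON-serializable report."""
    max_lag = max_lag or max(1, len(series) // 4)
    tau = estimate_delay(series, max_lag=max_lag)
    fnn = estimate_embedding_dim(series, tau=tau, r0=r0, m_max=m_max)
    traj = embed(series, EmbeddingParams(tau=tau, m=fnn.m, r0=r0))
    curve = correlation_dimension(traj)
    lam = lyapunov_wolf(traj, dt=1.0 / series.sampling_rate)
    surrogate_p = None
    if run_surrogates:
        surrogate_p = surrogate_test(
            series, statistic="lambda1", n_surrogates=n_surrogates,
            seed=seed, tau=tau, m=fnn.m,
        ).rank_p
    report = {
        "name": series.name,
        "sampling_rate": series.sampling_rate,
        "tau": tau,
        "m": fnn.m,
        "fnn_curve": fnn.fractions.tolist(),
        "fnn_converged": fnn.converged,
        "d2": curve.slope,
        "fit_lo": curve.fit_lo,
        "fit_hi": curve.fit_hi,
        "lambda1": lam,
        "lambda1_units": "1/time-unit",
        "surrogate_p": surrogate_p,
        "parameters": {"max_lag": max_lag, "m_max": m_max, "r0": r0},
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
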
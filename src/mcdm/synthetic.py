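"""Synthetic signal generation.

Two families of fixtures are produced here:

* canonical dynamical systems (logistic map, Lorenz flow, sine, white
  noise) whose nonlinear invariants (correlation dimension, largest
  Lyapunov exponent) are known analytically or from the literature, used
  to validate the phase-space estimators;
* a two-class synthetic magnetocardiogram (MCG) generator that emulates
  36-channel recordings of PQRST-like cardiac cycles with ground-truth
  fiducial annotations.  The ischemic class differs from the healthy one
  by a sustained ST-segment baseline offset, a reduced T-wave amplitude
  and larger beat-to-beat cycle-length variability — the classic surface
  signatures of myocardial ischemia.  The waveform model is a sum of
  Gaussian bumps and is a morphological stand-in, not a biophysically
  calibrated forward model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "FiducialSet",
    "MCGRecord",
    "simulate_system",
    "simulate_mcg",
    "simulate_cohort",
    "DEFAULT_MORPHOLOGY",
    "subject_seed",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : ndarray
        Signal amplitudes (arbitrary units; nominally pT for cardiac
        magnetic signals).
    sampling_rate : float
        Samples per second (or per iterate, for maps), > 0.
    name : str
        Free-text identifier.
    """

    values: np.ndarray
    sampling_rate: float
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if values.size < 1:
            raise ValueError("TimeSeries must contain at least one sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (length / sampling_rate)."""
        return self.values.size / self.sampling_rate


# Temporal order of the per-cycle fiducial boundaries used for validation.
_FIDUCIAL_ORDER = ("p_on", "p_off", "qrs_on", "r_peak", "qrs_off", "t_on", "t_off")


@dataclass(frozen=True)
class FiducialSet:
    """Per-cycle fiducial sample indices of a cardiac record.

    ``st_end`` marks the end of the ST segment and coincides with
    ``t_on`` in the synthetic generator; ``cycle_start``/``cycle_end``
    delimit the full beat so that the seven canonical segments (pre-P, P,
    post-P, QRS, ST, T, post-T) partition it exactly.
    """

    cycle_start: np.ndarray
    p_on: np.ndarray
    p_off: np.ndarray
    qrs_on: np.ndarray
    r_peak: np.ndarray
    qrs_off: np.ndarray
    st_end: np.ndarray
    t_on: np.ndarray
    t_off: np.ndarray
    cycle_end: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in self._array_fields():
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"fiducial field {name!r} must be 1-D")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all fiducial fields must have equal length")
            arrays[name] = arr
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        # strict temporal ordering within each cycle
        seq = np.stack(
            [arrays["cycle_start"]]
            + [arrays[f] for f in _FIDUCIAL_ORDER]
            + [arrays["cycle_end"]]
        )
        if not np.all(np.diff(seq, axis=0) > 0):
            raise ValueError("fiducial indices must be strictly increasing within each cycle")
        if not np.all(arrays["st_end"] == arrays["t_on"]):
            raise ValueError("st_end must coincide with t_on")

    @staticmethod
    def _array_fields() -> tuple[str, ...]:
        return (
            "cycle_start", "p_on", "p_off", "qrs_on", "r_peak",
            "qrs_off", "st_end", "t_on", "t_off", "cycle_end",
        )

    @property
    def n_cycles(self) -> int:
        return int(self.r_peak.size)

    def to_dict(self) -> dict[str, list[int]]:
        return {name: getattr(self, name).tolist() for name in self._array_fields()}

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence[int]]) -> "FiducialSet":
        return cls(**{name: np.asarray(data[name]) for name in cls._array_fields()})


@dataclass(frozen=True)
class MCGRecord:
    """A multi-channel cardiac magnetic recording.

    ``channels`` has shape (n_channels, n_samples); all channels share the
    sampling rate.  ``class_label`` is ``"healthy"``, ``"ischemic"`` or
    ``None`` (unlabelled).
    """

    channels: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    class_label: str | None = None
    fiducials: FiducialSet | None = None

    def __post_init__(self) -> None:
        channels = np.asarray(self.channels, dtype=float)
        if channels.ndim != 2:
            raise ValueError("channels must be a 2-D (n_channels x n_samples) array")
        if channels.shape[1] < 1:
            raise ValueError("channels must contain at least one sample")
        if not np.all(np.isfinite(channels)):
            raise ValueError("channel values must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.class_label not in (None, "healthy", "ischemic"):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.fiducials is not None and np.any(self.fiducials.cycle_end > channels.shape[1]):
            raise ValueError("fiducial indices exceed record length")
        object.__setattr__(self, "channels", channels)

    @property
    def n_channels(self) -> int:
        return int(self.channels.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.channels.shape[1])


# ---------------------------------------------------------------------------
# canonical dynamical systems
# ---------------------------------------------------------------------------

def _simulate_logistic(params: Mapping[str, Any], n_samples: int) -> tuple[np.ndarray, float]:
    r = float(params.get("r", 4.0))
    x0 = float(params.get("x0", 0.3))
    if not 0.0 < r <= 4.0:
        raise ValueError("logistic parameter r must lie in (0, 4]")
    if not 0.0 < x0 < 1.0:
        raise ValueError("logistic initial condition x0 must lie in (0, 1)")
    x = np.empty(n_samples)
    x[0] = x0
    for i in range(1, n_samples):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x, 1.0


def _lorenz_rhs(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def _simulate_lorenz(params: Mapping[str, Any], n_samples: int) -> tuple[np.ndarray, float]:
    sigma = float(params.get("sigma", 10.0))
    rho = float(params.get("rho", 28.0))
    beta = float(params.get("beta", 8.0 / 3.0))
    dt = float(params.get("dt", 0.01))
    transient = int(params.get("transient", 1000))
    state = np.asarray(params.get("initial_state", (1.0, 1.0, 1.0)), dtype=float)
    if dt <= 0:
        raise ValueError("lorenz dt must be positive")
    if transient < 0:
        raise ValueError("lorenz transient must be non-negative")
    if state.shape != (3,):
        raise ValueError("lorenz initial_state must have three components")

    out = np.empty(n_samples)
    # fixed-step classical 4th-order Runge-Kutta
    for i in range(transient + n_samples):
        if i >= transient:
            out[i - transient] = state[0]
        k1 = _lorenz_rhs(state, sigma, rho, beta)
        k2 = _lorenz_rhs(state + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_rhs(state + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_rhs(state + dt * k3, sigma, rho, beta)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return out, 1.0 / dt


def _simulate_sine(params: Mapping[str, Any], n_samples: int) -> tuple[np.ndarray, float]:
    fs = float(params.get("sampling_rate", 1000.0))
    frequency = float(params.get("frequency", 10.0))
    amplitude = float(params.get("amplitude", 1.0))
    phase = float(params.get("phase", 0.0))
    if fs <= 0:
        raise ValueError("sine sampling_rate must be positive")
    if not 0 < frequency < fs / 2:
        raise ValueError("sine frequency must lie below the Nyquist frequency")
    t = np.arange(n_samples) / fs
    return amplitude * np.sin(2 * np.pi * frequency * t + phase), fs


def _simulate_white_noise(
    params: Mapping[str, Any], n_samples: int, seed: int
) -> tuple[np.ndarray, float]:
    fs = float(params.get("sampling_rate", 1.0))
    sd = float(params.get("sd", 1.0))
    if sd <= 0:
        raise ValueError("white_noise sd must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, n_samples), fs


def simulate_system(
    name: str,
    params: Mapping[str, Any] | None = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> TimeSeries:
    """Generate a canonical test series with known dynamical invariants.

    Parameters
    ----------
    name : {"logistic", "lorenz", "sine", "white_noise"}
        System to simulate.  The logistic map is returned as its orbit,
        the Lorenz flow as the x-coordinate of a fixed-step 4th-order
        Runge-Kutta integration after discarding a transient.
    params : mapping, optional
        System parameters; unspecified entries fall back to the standard
        chaotic/periodic regimes (logistic ``r=4, x0=0.3``; Lorenz
        ``sigma=10, rho=28, beta=8/3, dt=0.01, transient=1000``).
    n_samples : int
        Number of samples to return (>= 2).
    seed : int
        Seed for stochastic systems (white noise); deterministic systems
        ignore it but the output remains reproducible either way.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    params = dict(params or {})
    if name == "logistic":
        values, fs = _simulate_logistic(params, n_samples)
    elif name == "lorenz":
        values, fs = _simulate_lorenz(params, n_samples)
    elif name == "sine":
        values, fs = _simulate_sine(params, n_samples)
    elif name == "white_noise":
        values, fs = _simulate_white_noise(params, n_samples, seed)
    else:
        raise ValueError(f"unknown system {name!r}")
    return TimeSeries(values=values, sampling_rate=fs, name=name)


# ---------------------------------------------------------------------------
# synthetic magnetocardiograms
# ---------------------------------------------------------------------------

#: Default PQRST morphology.  Amplitudes are in units of the R amplitude
#: (nominally ~1 a.u. == full deflection); centers/widths in seconds
#: relative to the R peak; the R peak sits at ``r_position`` of the cycle.
DEFAULT_MORPHOLOGY: dict[str, Any] = {
    "cycle_duration": 1.0,       # s, mean beat length (~60 bpm)
    "r_position": 0.4,           # R-peak location as a fraction of the cycle
    "amplitudes": {"P": 0.15, "Q": -0.10, "R": 1.0, "S": -0.15, "T": 0.35},
    "widths": {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.05},
    "offsets": {"P": -0.20, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.30},
    "noise_sd": 0.02,            # additive sensor noise, in R-amplitude units
    "gain_sd": 0.05,             # per-channel multiplicative gain spread
    "n_channels": 36,
    "cycle_jitter_sd": None,     # None -> class default (healthy 1%, ischemic 3%)
    "st_offset": -0.1,           # ischemic ST baseline shift, x R amplitude
    "t_scale": 0.5,              # ischemic T-amplitude multiplier
}

_JITTER_DEFAULTS = {"healthy": 0.01, "ischemic": 0.03}


def _merge_morphology(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = copy.deepcopy(DEFAULT_MORPHOLOGY)
    for key, value in (overrides or {}).items():
        if key not in merged:
            raise ValueError(f"unknown morphology parameter {key!r}")
        if isinstance(merged[key], dict):
            unknown = set(value) - set(merged[key])
            if unknown:
                raise ValueError(f"unknown wave keys {sorted(unknown)} in {key!r}")
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def simulate_mcg(
    class_label: str,
    n_cycles: int = 10,
    sampling_rate: float = 1000.0,
    morphology_params: Mapping[str, Any] | None = None,
    seed: int = 0,
    subject_id: str = "",
) -> MCGRecord:
    """Simulate a 36-channel MCG-like record with known fiducials.

    Each cycle is a sum of Gaussian bumps (P, Q, R, S, T) on a flat
    baseline.  The ischemic class adds a constant ST-segment baseline
    offset (default -0.1 x R amplitude), scales the T amplitude (default
    0.5x) and uses larger beat-to-beat cycle-length jitter.  All channels
    share the template, with independent Gaussian sensor noise and a
    small per-channel gain.  Fiducials are returned exactly as
    constructed; segment boundaries are placed at +-3 sigma of the P, QRS
    and T bumps so the seven segments partition every cycle.
    """
    if class_label not in ("healthy", "ischemic"):
        raise ValueError(f"class_label must be 'healthy' or 'ischemic', got {class_label!r}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    if sampling_rate < 250:
        raise ValueError("sampling_rate must be at least 250 Hz")

    p = _merge_morphology(morphology_params)
    amps, widths, offsets = p["amplitudes"], p["widths"], p["offsets"]
    for wave in ("P", "R", "T"):
        if amps[wave] <= 0:
            raise ValueError(f"{wave}-wave amplitude must be positive")
    for wave, w in widths.items():
        if w <= 0:
            raise ValueError(f"{wave}-wave width must be positive")

    jitter_sd = p["cycle_jitter_sd"]
    if jitter_sd is None:
        jitter_sd = _JITTER_DEFAULTS[class_label]

    rng = np.random.default_rng(seed)
    base = float(p["cycle_duration"])
    eps = rng.normal(0.0, 1.0, n_cycles) * jitter_sd
    eps = np.clip(eps, -3 * max(jitter_sd, 1e-12), 3 * max(jitter_sd, 1e-12))
    durations = base * (1.0 + eps)
    cycle_samples = np.round(durations * sampling_rate).astype(int)
    if np.any(cycle_samples < 4):
        raise ValueError("cycle duration incompatible with sampling_rate")

    t_amp = amps["T"] * (p["t_scale"] if class_label == "ischemic" else 1.0)
    wave_amps = {**amps, "T": t_amp}

    segments: list[np.ndarray] = []
    fid: dict[str, list[int]] = {name: [] for name in FiducialSet._array_fields()}
    start = 0
    for k in range(n_cycles):
        n_k = int(cycle_samples[k])
        stretch = durations[k] / base
        t = np.arange(n_k) / sampling_rate
        r_time = p["r_position"] * durations[k]
        cycle = np.zeros(n_k)
        for wave in ("P", "Q", "R", "S", "T"):
            center = r_time + offsets[wave] * stretch
            width = widths[wave] * stretch
            cycle += wave_amps[wave] * np.exp(-0.5 * ((t - center) / width) ** 2)

        # segment boundaries at +-3 sigma of the bounding bumps
        bounds_s = {
            "p_on": offsets["P"] - 3 * widths["P"],
            "p_off": offsets["P"] + 3 * widths["P"],
            "qrs_on": offsets["Q"] - 3 * widths["Q"],
            "qrs_off": offsets["S"] + 3 * widths["S"],
            "t_on": offsets["T"] - 3 * widths["T"],
            "t_off": offsets["T"] + 3 * widths["T"],
        }
        idx = {
            name: int(round((r_time + off * stretch) * sampling_rate))
            for name, off in bounds_s.items()
        }
        idx["r_peak"] = int(round(r_time * sampling_rate))
        ordered = [0, idx["p_on"], idx["p_off"], idx["qrs_on"], idx["r_peak"],
                   idx["qrs_off"], idx["t_on"], idx["t_off"], n_k]
        if not all(b < a for b, a in zip(ordered, ordered[1:])):
            raise ValueError("cycle duration incompatible with sampling_rate")

        if class_label == "ischemic":
            cycle[idx["qrs_off"]:idx["t_on"]] += p["st_offset"] * amps["R"]

        segments.append(cycle)
        fid["cycle_start"].append(start)
        fid["cycle_end"].append(start + n_k)
        for name in ("p_on", "p_off", "qrs_on", "r_peak", "qrs_off", "t_on", "t_off"):
            fid[name].append(start + idx[name])
        fid["st_end"].append(start + idx["t_on"])
        start += n_k

    template = np.concatenate(segments)
    n_channels = int(p["n_channels"])
    if n_channels < 1:
        raise ValueError("n_channels must be at least 1")
    gains = 1.0 + rng.normal(0.0, p["gain_sd"], n_channels)
    noise = rng.normal(0.0, p["noise_sd"], (n_channels, template.size))
    channels = gains[:, None] * template[None, :] + noise

    return MCGRecord(
        channels=channels,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        class_label=class_label,
        fiducials=FiducialSet(**{k: np.asarray(v) for k, v in fid.items()}),
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Derive a per-subject seed from a master seed.

    Uses numpy's splittable ``SeedSequence`` keyed on (master, index) so
    that cohort members are reproducible element-wise regardless of
    generation order.
    """
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def simulate_cohort(
    n_healthy: int,
    n_ischemic: int,
    seed: int = 0,
    n_cycles: int = 10,
    sampling_rate: float = 1000.0,
    morphology_params: Mapping[str, Any] | None = None,
) -> list[MCGRecord]:
    """Simulate a labelled cohort of synthetic MCG records.

    Subject ids are ``H0001..`` and ``I0001..``; each subject's seed is
    derived deterministically from the master seed via
    :func:`subject_seed`.
    """
    if n_healthy < 0 or n_ischemic < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_healthy == 0 and n_ischemic == 0:
        raise ValueError("empty cohort")
    records = []
    for i in range(n_healthy + n_ischemic):
        if i < n_healthy:
            label, sid = "healthy", f"H{i + 1:04d}"
        else:
            label, sid = "ischemic", f"I{i - n_healthy + 1:04d}"
        records.append(
            simulate_mcg(
                class_label=label,
                n_cycles=n_cycles,
                sampling_rate=sampling_rate,
                morphology_params=morphology_params,
                seed=subject_seed(seed, i),
                subject_id=sid,
            )
        )
    return records
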
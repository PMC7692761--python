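"""Synthetic Raman-like spectrum generator.

Emulates the statistical structure the downstream analysis assumes:
two-component (pulp/rind) linear mixtures for the target class, an
amplitude-perturbed competitor class, a constant packaging contribution,
per-spectrum fluorescence baseline, additive noise, and a rigid
wavenumber shift plus gain between measurement sessions.  Every random
draw flows from a single seed so identical configs give bit-identical
datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectraMatrix

__all__ = [
    "BandSpec",
    "ComponentProfile",
    "GeneratorConfig",
    "SyntheticDataset",
    "make_component_profiles",
    "synthesize_spectrum",
    "generate_dataset",
]


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: center / half-width / amplitude / line shape."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, axis: np.ndarray, shift: float = 0.0) -> np.ndarray:
        x = axis - (self.center + shift)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * (x / self.width) ** 2)
        return self.amplitude * self.width**2 / (x**2 + self.width**2)


@dataclass(frozen=True)
class ComponentProfile:
    """Named mixture component as a sum of bands."""

    name: str
    bands: tuple[BandSpec, ...]

    def evaluate(self, axis: np.ndarray, shift: float = 0.0) -> np.ndarray:
        out = np.zeros_like(axis, dtype=float)
        for b in self.bands:
            out += b.evaluate(axis, shift)
        return out

    def amplitudes(self) -> dict[float, float]:
        return {b.center: b.amplitude for b in self.bands}


# Shared cheese band skeleton: (center cm^-1, half-width cm^-1, pulp amplitude).
# Centers follow the usual cheese/casein assignments (CH deformation near
# 1440, amide III 1260-1340, Phe ~1003, phosphorylated casein markers at
# 1003/980/850/830, C-C/C-N stretches 930-1150).
_CHEESE_BANDS: list[tuple[float, float, float]] = [
    (1440.0, 18.0, 1.00),
    (1340.0, 15.0, 0.34),
    (1300.0, 14.0, 0.30),
    (1260.0, 13.0, 0.28),
    (1150.0, 10.0, 0.38),
    (1124.0, 9.0, 0.30),
    (1065.0, 10.0, 0.42),
    (1003.0, 7.0, 0.55),
    (980.0, 9.0, 0.22),
    (940.0, 9.0, 0.30),
    (930.0, 9.0, 0.26),
    (850.0, 8.0, 0.28),
    (830.0, 8.0, 0.24),
]

# Rind-vs-pulp amplitude deltas on the phosphorylation-sensitive set.
_RIND_DELTAS = {1003.0: +0.22, 980.0: +0.30, 850.0: +0.18, 830.0: +0.14,
                1440.0: -0.10}

# Competitor: same chemistry family, different recipe -> >=3 amplitudes off.
_COMPETITOR_FACTORS = {1440.0: 0.80, 1065.0: 0.65, 1003.0: 1.45, 850.0: 1.35,
                       1150.0: 1.25}

# Polymer bag contribution (polyethylene/polyamide-like bands).
_PACKAGING_BANDS: list[tuple[float, float, float]] = [
    (1062.0, 7.0, 0.10),
    (1128.0, 7.0, 0.09),
    (1296.0, 8.0, 0.12),
    (1440.0, 9.0, 0.07),
    (1640.0, 12.0, 0.06),
]


def make_component_profiles(
    seed: int, shape: str = "gaussian"
) -> list[ComponentProfile]:
    """Build the four mixture components (pulp, rind, packaging, competitor).

    The seed applies a small (<=2 %) amplitude jitter so distinct seeds give
    distinct but structurally identical chemistries; the pulp/rind and
    pulp/competitor amplitude contrasts are preserved for every seed.
    """
    rng = np.random.default_rng(seed)

    def jitter() -> float:
        return float(1.0 + 0.02 * rng.uniform(-1.0, 1.0))

    pulp = []
    rind = []
    competitor = []
    for center, width, amp in _CHEESE_BANDS:
        a = amp * jitter()
        pulp.append(BandSpec(center, width, a, shape))
        rind.append(
            BandSpec(center, width, max(a + _RIND_DELTAS.get(center, 0.0), 0.0),
                     shape)
        )
        competitor.append(
            BandSpec(center, width, a * _COMPETITOR_FACTORS.get(center, 1.0),
                     shape)
        )
    packaging = [
        BandSpec(c, w, a * jitter(), shape) for c, w, a in _PACKAGING_BANDS
    ]
    return [
        ComponentProfile("pulp", tuple(pulp)),
        ComponentProfile("rind", tuple(rind)),
        ComponentProfile("packaging", tuple(packaging)),
        ComponentProfile("competitor", tuple(competitor)),
    ]


@dataclass
class GeneratorConfig:
    """Full statistical description of one synthetic acquisition campaign.

    Defaults mimic the study layout: 80 target packages (28 compliant with
    rind 8-18 % w/w, 52 above 18 %), 10 extra target unknowns, 10
    competitor packages, two measurement sessions with a rigid +4 cm^-1
    shift and 5 % gain on the second, five point spectra per package, and
    extra replicate acquisitions for one package per role.
    """

    axis_start: float = 400.0
    axis_stop: float = 2300.0
    axis_step: float = 2.0
    n_target: int = 80
    n_compliant: int = 28
    n_unknown: int = 10
    n_nontarget: int = 10
    rind_fraction_range: tuple[float, float] = (8.0, 42.0)
    compliant_range: tuple[float, float] = (8.0, 18.0)
    sessions: int = 2
    session_shifts: tuple[float, ...] = (0.0, 4.0)
    session_gains: tuple[float, ...] = (1.0, 1.05)
    # Per-session multiplier on the rind component: models the systematic
    # production-period drift that biases a single-session calibration.
    rind_gain_by_session: tuple[float, ...] = (1.0, 0.85)
    baseline_amplitude: float = 0.30
    noise_sd: float = 0.01
    points_per_package: int = 5
    point_gain_sd: float = 0.02
    # role -> number of extra acquisitions of that role's first package
    replicate_plan: dict[str, int] = field(
        default_factory=lambda: {
            "PR1st": 4, "PR2nd": 6, "PR-unknown": 1, "notPR": 2
        }
    )
    band_shape: str = "gaussian"
    profile_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rind_fraction_range
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError("rind_fraction_range must be within [0, 100]")
        if self.axis_step <= 0 or self.axis_stop <= self.axis_start:
            raise ValueError("invalid axis definition")
        if len(self.session_shifts) < self.sessions:
            raise ValueError("one shift per session required")
        if len(self.session_gains) < self.sessions:
            raise ValueError("one gain per session required")
        if self.points_per_package < 1:
            raise ValueError("points_per_package must be >= 1")

    @property
    def axis(self) -> np.ndarray:
        return np.arange(
            self.axis_start, self.axis_stop + self.axis_step / 2,
            self.axis_step,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """Point spectra + per-spectrum metadata + per-package ground truth."""

    spectra: SpectraMatrix
    meta: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _baseline(axis: np.ndarray, amplitude: float,
              rng: np.random.Generator) -> np.ndarray:
    """Smooth fluorescence-like drift: cubic polynomial + exponential hump."""
    if amplitude == 0.0:
        return np.zeros_like(axis)
    x = (axis - axis[0]) / (axis[-1] - axis[0])
    coeffs = rng.uniform(-1.0, 1.0, size=4)
    poly = coeffs[0] + coeffs[1] * x + coeffs[2] * x**2 + coeffs[3] * x**3
    tau = rng.uniform(0.25, 0.6)
    hump = rng.uniform(0.5, 1.5) * np.exp(-x / tau)
    return amplitude * (poly - poly.min() + hump)


def synthesize_spectrum(
    mix: dict[str, float],
    profiles: dict[str, ComponentProfile] | list[ComponentProfile],
    config: GeneratorConfig,
    session: int,
    rng: np.random.Generator | int,
) -> Spectrum:
    """Render one point spectrum from a component mixture.

    ``mix`` maps component names to non-negative weights.  Target-class
    mixtures (no competitor involved) must satisfy
    weight(pulp) + weight(rind) == 1.  The session applies a rigid band
    shift and a multiplicative gain; the packaging component is always
    added with unit weight.
    """
    if isinstance(profiles, list):
        profiles = {p.name: p for p in profiles}
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not 0 <= session < config.sessions:
        raise ValueError(f"session {session} outside 0..{config.sessions - 1}")
    for name, w in mix.items():
        if w < 0:
            raise ValueError(f"negative weight for {name!r}")
        if name not in profiles:
            raise ValueError(f"unknown component {name!r}")
    if "competitor" not in mix:
        total = mix.get("pulp", 0.0) + mix.get("rind", 0.0)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"target-class pulp+rind weights must sum to 1, got {total}"
            )

    axis = config.axis
    shift = config.session_shifts[session]
    gain = config.session_gains[session]
    rind_gain = (
        config.rind_gain_by_session[session]
        if session < len(config.rind_gain_by_session) else 1.0
    )
    signal = np.zeros_like(axis)
    for name, w in mix.items():
        w_eff = w * rind_gain if name == "rind" else w
        signal += w_eff * profiles[name].evaluate(axis, shift)
    signal += profiles["packaging"].evaluate(axis, shift)
    signal *= gain
    signal = signal + _baseline(axis, config.baseline_amplitude, rng)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=axis.size)
    return Spectrum(axis, signal)


def _package_plan(config: GeneratorConfig) -> list[dict]:
    """Deterministic package skeleton: ids, roles, classes, sessions."""
    plan: list[dict] = []
    n_session1 = config.n_target // 2
    for i in range(config.n_target):
        role = "PR1st" if i < n_session1 else "PR2nd"
        session = 0 if role == "PR1st" else min(1, config.sessions - 1)
        plan.append(
            {"package_id": f"PR{i + 1:03d}", "role": role, "class": "PR",
             "session": session}
        )
    for i in range(config.n_unknown):
        plan.append(
            {"package_id": f"UNK{i + 1:03d}", "role": "PR-unknown",
             "class": "PR", "session": min(1, config.sessions - 1)}
        )
    for i in range(config.n_nontarget):
        plan.append(
            {"package_id": f"NPR{i + 1:03d}", "role": "notPR",
             "class": "notPR", "session": min(1, config.sessions - 1)}
        )
    seen: set[str] = set()
    for pkg in plan:
        extra = 0
        if pkg["role"] in config.replicate_plan and pkg["role"] not in seen:
            extra = int(config.replicate_plan[pkg["role"]])
            seen.add(pkg["role"])
        pkg["n_acq"] = 1 + extra
    return plan


def _draw_rind_fractions(config: GeneratorConfig,
                         rng: np.random.Generator) -> dict[str, float]:
    """True rind % per target package honouring the compliant quota."""
    lo, hi = config.rind_fraction_range
    clo, chi = config.compliant_range
    out: dict[str, float] = {}
    # compliant quota split across the two target blocks (sessions)
    n_c1 = config.n_compliant // 2
    n_s1 = config.n_target // 2
    for i in range(config.n_target):
        pid = f"PR{i + 1:03d}"
        within = i if i < n_s1 else i - n_s1
        quota = n_c1 if i < n_s1 else config.n_compliant - n_c1
        if within < quota:
            out[pid] = float(rng.uniform(max(lo, clo), chi))
        else:
            out[pid] = float(rng.uniform(max(chi, lo) + 0.3, hi))
    for i in range(config.n_unknown):
        out[f"UNK{i + 1:03d}"] = float(rng.uniform(lo, hi))
    return out


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full campaign of point spectra.

    Each package yields ``n_acq`` acquisitions (1 + planned replicates),
    each acquisition ``points_per_package`` point spectra sharing the
    package mixture but with independent point gain, baseline and noise.
    """
    rng = np.random.default_rng(config.seed)
    profiles = {
        p.name: p
        for p in make_component_profiles(config.profile_seed,
                                         config.band_shape)
    }
    plan = _package_plan(config)
    rind = _draw_rind_fractions(config, rng)
    axis = config.axis

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    for pkg in plan:
        pid = pkg["package_id"]
        session = pkg["session"]
        if pkg["class"] == "PR":
            f = rind[pid] / 100.0
            mix = {"pulp": 1.0 - f, "rind": f}
            rind_pct: float = rind[pid]
        else:
            mix = {"competitor": 1.0}
            rind_pct = float("nan")
        truth_rows.append(
            {"package_id": pid, "class": pkg["class"], "rind_pct": rind_pct,
             "role": pkg["role"], "session": session}
        )
        shift = config.session_shifts[session]
        gain = config.session_gains[session]
        rind_gain = (
            config.rind_gain_by_session[session]
            if session < len(config.rind_gain_by_session) else 1.0
        )
        signal = np.zeros_like(axis)
        for name, w in mix.items():
            w_eff = w * rind_gain if name == "rind" else w
            signal += w_eff * profiles[name].evaluate(axis, shift)
        signal += profiles["packaging"].evaluate(axis, shift)
        signal *= gain
        for a in range(pkg["n_acq"]):
            acq_id = f"{pid}_a{a}"
            for j in range(config.points_per_package):
                g = 1.0 + config.point_gain_sd * rng.standard_normal()
                y = g * signal + _baseline(
                    axis, config.baseline_amplitude, rng
                )
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, size=axis.size)
                sid = f"{acq_id}_p{j}"
                rows.append(y)
                meta_rows.append(
                    {
                        "spectrum_id": sid,
                        "package_id": pid,
                        "class": pkg["class"],
                        "rind_pct": rind_pct,
                        "session": session,
                        "replicate_group": acq_id,
                        "point_index": j,
                        "role": pkg["role"],
                    }
                )
    spectra = SpectraMatrix(
        axis, np.vstack(rows), [m["spectrum_id"] for m in meta_rows]
    )
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(spectra=spectra, meta=meta, truth=truth,
                            config=config)
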
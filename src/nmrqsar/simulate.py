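"""Synthetic data generators.

Two generators mirror the statistical structure the pipelines assume:

* :func:`gen_spectra` emits two-class collections of NMR peak lists in
  which a small set of planted "informative" bins is occupied with a
  higher probability among actives than inactives, over a uniform
  per-bin background;
* :func:`gen_regression` emits descriptor tables with a sparse linear
  signal mapping to a continuous activity target.

Both are deterministic per seed and emit the same formats the readers
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import EXTRACT_ACTIVE, EXTRACT_INACTIVE
from .binning import BinningScheme, PeakList, make_scheme


class SimulationError(ValueError):
    pass


def default_schemes() -> tuple[BinningScheme, BinningScheme]:
    """The 0.1-ppm proton / 0.5-ppm carbon pair (120 + 400 = 520 bins)."""
    return make_scheme("1H", 0.1), make_scheme("13C", 0.5)


#: Default planted signal: eight informative bins across both nuclei.
DEFAULT_INFORMATIVE_BINS = (
    ("1H", 14),
    ("1H", 2),
    ("1H", 44),
    ("1H", 52),
    ("13C", 151),
    ("13C", 170),
    ("13C", 280),
    ("13C", 352),
)


@dataclass
class SpectraSimConfig:
    n_active: int = 60
    n_inactive: int = 60
    informative_bins: tuple = DEFAULT_INFORMATIVE_BINS
    p_informative_active: float = 0.9
    p_informative_inactive: float = 0.2
    p_background: float = 0.05
    peaks_per_sample: float = 0.0   # extra uniformly placed peaks (Poisson mean)
    shift_jitter: str = "uniform"   # "uniform" within bin | "gaussian" across edges
    gaussian_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_informative_active", "p_informative_inactive", "p_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.p_informative_active <= self.p_informative_inactive:
            raise SimulationError(
                "p_informative_active must exceed p_informative_inactive "
                "for a learnable signal"
            )
        if self.n_active < 0 or self.n_inactive < 0:
            raise SimulationError("sample counts must be non-negative")


def _bin_interval(scheme_h, scheme_c, nucleus: str, k: int) -> tuple[float, float]:
    scheme = scheme_h if nucleus == "1H" else scheme_c
    if not 1 <= k <= scheme.n_bins:
        raise SimulationError(
            f"informative bin ({nucleus}, {k}) outside scheme range 1..{scheme.n_bins}"
        )
    return scheme.bin_edges(k)


def gen_spectra(
    config: SpectraSimConfig,
    scheme_h: BinningScheme | None = None,
    scheme_c: BinningScheme | None = None,
) -> tuple[list[PeakList], list[str]]:
    """Generate labeled peak lists with a planted informative-bin signal.

    Actives occupy each informative bin with ``p_informative_active``,
    inactives with ``p_informative_inactive``; every other bin is occupied
    with ``p_background``.  An occupied bin holds one peak at a shift
    drawn uniformly within the bin (so bin identity is exact ground
    truth), unless ``shift_jitter="gaussian"`` adds edge-crossing noise.
    """
    if scheme_h is None or scheme_c is None:
        scheme_h, scheme_c = default_schemes()
    for nucleus, k in config.informative_bins:
        _bin_interval(scheme_h, scheme_c, nucleus, k)
    rng = np.random.default_rng(config.seed)
    informative = set(config.informative_bins)

    peaklists: list[PeakList] = []
    labels: list[str] = []
    specs = [(EXTRACT_ACTIVE, config.p_informative_active)] * config.n_active + [
        (EXTRACT_INACTIVE, config.p_informative_inactive)
    ] * config.n_inactive
    for i, (label, p_inf) in enumerate(specs):
        peaks: list[tuple[str, float, float]] = []
        for scheme in (scheme_h, scheme_c):
            for k in range(1, scheme.n_bins + 1):
                key = (scheme.nucleus, k)
                p = p_inf if key in informative else config.p_background
                if p > 0 and rng.random() < p:
                    lo, hi = scheme.bin_edges(k)
                    shift = rng.uniform(lo, hi)
                    if config.shift_jitter == "gaussian" and config.gaussian_jitter_sd > 0:
                        shift += rng.normal(0.0, config.gaussian_jitter_sd)
                    peaks.append((scheme.nucleus, float(shift), float(rng.uniform(0.1, 1.0))))
        for _ in range(rng.poisson(config.peaks_per_sample)):
            scheme = scheme_h if rng.random() < 0.5 else scheme_c
            shift = rng.uniform(scheme.lo, scheme.hi)
            peaks.append((scheme.nucleus, float(shift), float(rng.uniform(0.1, 1.0))))
        peaks = [
            (n, s, v)
            for (n, s, v) in peaks
            if (scheme_h if n == "1H" else scheme_c).lo
            <= s
            < (scheme_h if n == "1H" else scheme_c).hi
        ]
        peaklists.append(PeakList(sample_id=f"sim-{i:04d}", peaks=peaks))
        labels.append(label)
    return peaklists, labels


def informative_joint_indices(
    config: SpectraSimConfig,
    scheme_h: BinningScheme | None = None,
    scheme_c: BinningScheme | None = None,
) -> list[int]:
    """1-based joint indices of the planted informative bins."""
    if scheme_h is None or scheme_c is None:
        scheme_h, scheme_c = default_schemes()
    out = []
    for nucleus, k in config.informative_bins:
        out.append(k if nucleus == "1H" else scheme_h.n_bins + k)
    return sorted(out)


@dataclass
class RegressionSimConfig:
    n: int = 200
    p: int = 50
    k_informative: int = 5
    beta: tuple = ()
    intercept: float = 5.0
    noise_sd: float = 0.3
    binary_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p:
            raise SimulationError("k_informative must not exceed p")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if not self.beta:
            self.beta = tuple(1.0 + 0.25 * j for j in range(self.k_informative))
        if len(self.beta) != self.k_informative:
            raise SimulationError("beta length must equal k_informative")


def gen_regression(config: RegressionSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate (X, y) with ``y = intercept + X[:, :k] @ beta + noise``.

    The first ``k_informative`` columns carry the signal; the rest are
    pure noise.  Features are standard normal, or Bernoulli(0.5) when
    ``binary_features`` is set.
    """
    rng = np.random.default_rng(config.seed)
    if config.binary_features:
        X = rng.integers(0, 2, size=(config.n, config.p)).astype(float)
    else:
        X = rng.standard_normal((config.n, config.p))
    beta = np.asarray(config.beta, dtype=float)
    y = config.intercept + X[:, : config.k_informative] @ beta
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=config.n)
    return X, y
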
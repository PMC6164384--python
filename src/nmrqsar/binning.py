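"""Fixed-width chemical-shift binning of 1D NMR peak lists.

A :class:`BinningScheme` partitions a nominal chemical-shift range into
contiguous, half-open, fixed-width bins.  Peak lists are reduced to
per-bin descriptor vectors (binary occupancy, peak count, or summed
intensity) and assembled into sample x descriptor matrices whose columns
follow a joint index: the full block of proton bins first, then the full
block of carbon bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEI = ("1H", "13C")

#: Default lower edges of bin 1, chosen so that standard 0.1-ppm proton /
#: 0.5-ppm carbon grids land on the documented descriptor intervals
#: (e.g. proton bin 14 covers [1.3019, 1.4019)).
DEFAULT_ORIGIN = {"1H": 0.0019, "13C": -0.0073}

#: Nominal usable chemical-shift ranges in ppm.
DEFAULT_SPAN = {"1H": (0.0, 12.0), "13C": (0.0, 200.0)}


class BinningError(ValueError):
    """Raised for invalid binning schemes or unmappable inputs."""


def _check_nucleus(nucleus: str) -> str:
    if nucleus not in NUCLEI:
        raise BinningError(f"unknown nucleus {nucleus!r}; expected one of {NUCLEI}")
    return nucleus


@dataclass(frozen=True)
class BinningScheme:
    """A fixed-width, half-open partition of a chemical-shift range.

    Bin ``k`` (1-based) covers ``[origin + (k-1)*width, origin + k*width)``.
    ``n_bins`` defaults to ``floor((span_hi - span_lo) / width)`` but may be
    overridden explicitly (some published bin counts include one extra bin
    that plain floor division does not produce).
    """

    nucleus: str
    width: float
    origin: float
    span_lo: float
    span_hi: float
    n_bins: int

    def __post_init__(self) -> None:
        _check_nucleus(self.nucleus)
        if not (self.width > 0 and math.isfinite(self.width)):
            raise BinningError(f"bin width must be positive and finite, got {self.width}")
        if not self.span_hi > self.span_lo:
            raise BinningError("span must be non-empty")
        if self.span_hi - self.span_lo < self.width:
            raise BinningError("span shorter than one bin")
        if self.n_bins < 1:
            raise BinningError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def lo(self) -> float:
        """Lower edge of the first bin."""
        return self.origin

    @property
    def hi(self) -> float:
        """Upper edge of the last bin (exclusive)."""
        return self.origin + self.n_bins * self.width

    def bin_edges(self, k: int) -> tuple[float, float]:
        """Return the ``[lo, hi)`` edges of 1-based bin ``k``."""
        if not 1 <= k <= self.n_bins:
            raise BinningError(f"bin {k} out of range 1..{self.n_bins}")
        lo = self.origin + (k - 1) * self.width
        return lo, lo + self.width


def make_scheme(
    nucleus: str,
    width: float,
    origin: float | None = None,
    span: tuple[float, float] | None = None,
    n_bins: int | None = None,
) -> BinningScheme:
    """Build a :class:`BinningScheme`.

    Parameters
    ----------
    nucleus
        ``"1H"`` or ``"13C"``.
    width
        Bin width in ppm (> 0).
    origin
        Lower edge of bin 1; defaults to the calibrated per-nucleus offset
        in :data:`DEFAULT_ORIGIN`.
    span
        Nominal ``(lo, hi)`` shift range in ppm; defaults to 0-12 ppm for
        proton and 0-200 ppm for carbon.
    n_bins
        Explicit bin-count override; default ``floor(span_length / width)``.
    """
    _check_nucleus(nucleus)
    if origin is None:
        origin = DEFAULT_ORIGIN[nucleus]
    if span is None:
        span = DEFAULT_SPAN[nucleus]
    span_lo, span_hi = float(span[0]), float(span[1])
    if n_bins is None:
        if not width > 0:
            raise BinningError(f"bin width must be positive, got {width}")
        # guard against float fuzz when span is an exact multiple of width
        n_bins = int(math.floor((span_hi - span_lo) / width + 1e-9))
    return BinningScheme(
        nucleus=nucleus,
        width=float(width),
        origin=float(origin),
        span_lo=span_lo,
        span_hi=span_hi,
        n_bins=int(n_bins),
    )


def bin_index(scheme: BinningScheme, shift: float) -> int | None:
    """Map a chemical shift (ppm) to its 1-based bin number.

    Returns ``None`` for shifts outside ``[scheme.lo, scheme.hi)``.  Bins are
    half-open, so a shift exactly on a shared edge belongs to the upper bin.
    """
    if not math.isfinite(shift):
        raise BinningError(f"non-finite chemical shift: {shift}")
    u = (shift - scheme.origin) / scheme.width
    # a shift within 1e-9 bin-widths of an edge counts as on the edge and,
    # being half-open, belongs to the upper bin
    k = int(math.floor(u + 1e-9)) + 1
    if k < 1 or k > scheme.n_bins:
        return None
    return k


@dataclass
class PeakList:
    """Picked peaks of one sample: ``(nucleus, shift ppm, intensity)`` tuples."""

    sample_id: str
    peaks: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for nucleus, shift, intensity in self.peaks:
            _check_nucleus(nucleus)
            if not math.isfinite(shift):
                raise BinningError(f"non-finite shift in sample {self.sample_id!r}")
            if intensity < 0:
                raise BinningError(f"negative intensity in sample {self.sample_id!r}")

    def for_nucleus(self, nucleus: str) -> list[tuple[float, float]]:
        return [(s, i) for (n, s, i) in self.peaks if n == nucleus]


MODES = ("binary", "count", "intensity")


def joint_names(scheme_h: BinningScheme, scheme_c: BinningScheme) -> list[str]:
    """Descriptor names for the joint proton-then-carbon column index.

    Names look like ``H_0014[1.3019,1.4019)``.
    """
    names: list[str] = []
    for scheme, tag in ((scheme_h, "H"), (scheme_c, "C")):
        for k in range(1, scheme.n_bins + 1):
            lo, hi = scheme.bin_edges(k)
            names.append(f"{tag}_{k:04d}[{lo:.4f},{hi:.4f})")
    return names


def joint_bounds(
    scheme_h: BinningScheme, scheme_c: BinningScheme, joint_index: int
) -> tuple[str, float, float]:
    """Resolve a 1-based joint descriptor index to ``(nucleus, lo, hi)``.

    The proton block occupies joint indices ``1..n_H``, the carbon block
    ``n_H+1..n_H+n_C``.
    """
    n_h, n_c = scheme_h.n_bins, scheme_c.n_bins
    if not 1 <= joint_index <= n_h + n_c:
        raise BinningError(f"joint index {joint_index} out of range 1..{n_h + n_c}")
    if joint_index <= n_h:
        lo, hi = scheme_h.bin_edges(joint_index)
        return "1H", lo, hi
    lo, hi = scheme_c.bin_edges(joint_index - n_h)
    return "13C", lo, hi


def vectorize(
    peaklist: PeakList,
    scheme_h: BinningScheme,
    scheme_c: BinningScheme,
    mode: str = "binary",
    exclude_windows: Sequence[tuple[str, float, float]] | None = None,
) -> np.ndarray:
    """Reduce one peak list to a joint descriptor vector.

    Modes: ``binary`` (1 iff any peak in the bin), ``count`` (number of
    peaks), ``intensity`` (summed intensity).  Peaks outside the scheme
    range are dropped with a logged warning.  ``exclude_windows`` is an
    optional list of ``(nucleus, lo, hi)`` shift windows (e.g. residual
    solvent signals) whose peaks are masked out before binning.
    """
    if mode not in MODES:
        raise BinningError(f"unknown mode {mode!r}; expected one of {MODES}")
    n_h = scheme_h.n_bins
    vec = np.zeros(n_h + scheme_c.n_bins)
    n_dropped = 0
    for nucleus, shift, intensity in peaklist.peaks:
        if exclude_windows is not None and any(
            nucleus == w_nuc and w_lo <= shift < w_hi for w_nuc, w_lo, w_hi in exclude_windows
        ):
            continue
        scheme, offset = (scheme_h, 0) if nucleus == "1H" else (scheme_c, n_h)
        k = bin_index(scheme, shift)
        if k is None:
            n_dropped += 1
            continue
        j = offset + k - 1
        if mode == "binary":
            vec[j] = 1.0
        elif mode == "count":
            vec[j] += 1.0
        else:
            vec[j] += intensity
    if n_dropped:
        logger.warning(
            "sample %s: dropped %d peak(s) outside the binning range",
            peaklist.sample_id,
            n_dropped,
        )
    return vec


@dataclass
class DescriptorMatrix:
    """Samples x named descriptors, with the joint proton/carbon column index."""

    sample_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.descriptor_names)):
            raise BinningError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.descriptor_names)} descriptors"
            )
        if self.mode == "binary" and self.values.size:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise BinningError("binary descriptor matrix contains values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.descriptor_names,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, mode: str = "binary") -> "DescriptorMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            sample_ids=[str(s) for s in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            mode=mode,
        )


def build_matrix(
    peaklists: Iterable[PeakList],
    scheme_h: BinningScheme,
    scheme_c: BinningScheme,
    mode: str = "binary",
    exclude_windows: Sequence[tuple[str, float, float]] | None = None,
) -> DescriptorMatrix:
    """Assemble a :class:`DescriptorMatrix` from peak lists (input order kept)."""
    peaklists = list(peaklists)
    ids = [p.sample_id for p in peaklists]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise BinningError(f"duplicate sample ids: {dupes}")
    names = joint_names(scheme_h, scheme_c)
    if peaklists:
        values = np.vstack(
            [vectorize(p, scheme_h, scheme_c, mode, exclude_windows) for p in peaklists]
        )
    else:
        values = np.empty((0, len(names)))
    return DescriptorMatrix(sample_ids=ids, descriptor_names=names, values=values, mode=mode)
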
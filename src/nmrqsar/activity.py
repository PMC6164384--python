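"""IC50 / pIC50 transforms and activity-class labeling.

Two unit regimes exist and must not be mixed: pure molecules are assayed
in micromolar (uM) and carry a pIC50; crude extracts and fractions are
assayed in ug/mL, where no molar conversion is possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Class labels for the three-way molecule scheme.
ACTIVE_VERY = "active-to-very-active"
ACTIVE_MODERATE = "active-to-moderate-active"
INACTIVE = "inactive"

#: Class labels for the extract scheme.
EXTRACT_ACTIVE = "moderate-active-to-active"
EXTRACT_INACTIVE = "inactive"

#: Activity cutoffs.
MOLECULE_ACTIVE_UM = 10.0        # binary molecule scheme: active iff IC50 <= 10 uM
MOLECULE_MODERATE_UM = 50.0      # ternary scheme upper cutoff
EXTRACT_CUTOFF_UG_ML = 156.0     # extract scheme: active iff IC50 < 156 ug/mL


class ActivityError(ValueError):
    pass


def ic50_um_to_pic50(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 in mol/L) for a micromolar IC50.

    Equivalently ``6 - log10(ic50_um)``: 1 uM -> 6, 10 uM -> 5, 1 nM -> 9.
    """
    if not (ic50_um > 0 and math.isfinite(ic50_um)):
        raise ActivityError(f"IC50 must be positive and finite, got {ic50_um}")
    return 6.0 - math.log10(ic50_um)


def pic50_to_ic50_um(pic50: float) -> float:
    """Inverse of :func:`ic50_um_to_pic50`."""
    if not math.isfinite(pic50):
        raise ActivityError(f"pIC50 must be finite, got {pic50}")
    return 10.0 ** (6.0 - pic50)


def label_molecule(ic50_um: float, scheme: str = "ternary") -> str:
    """Activity class of a pure molecule from its micromolar IC50.

    ``scheme="binary"``: active iff IC50 <= 10 uM.
    ``scheme="ternary"``: < 10 uM active-to-very-active; [10, 50) uM
    active-to-moderate-active; >= 50 uM inactive.
    """
    if not ic50_um > 0:
        raise ActivityError(f"IC50 must be positive, got {ic50_um}")
    if scheme == "binary":
        return ACTIVE_VERY if ic50_um <= MOLECULE_ACTIVE_UM else INACTIVE
    if scheme == "ternary":
        if ic50_um < MOLECULE_ACTIVE_UM:
            return ACTIVE_VERY
        if ic50_um < MOLECULE_MODERATE_UM:
            return ACTIVE_MODERATE
        return INACTIVE
    raise ActivityError(f"unknown molecule scheme {scheme!r}")


def label_extract(ic50_ug_ml: float | None, censored: bool = False) -> str:
    """Activity class of an extract-type sample from its IC50 in ug/mL.

    Strict cutoff: active iff IC50 < 156 ug/mL.  Samples whose IC50 could
    not be determined within the tested concentration range are passed as
    ``censored=True`` and are always inactive.
    """
    if censored or ic50_ug_ml is None:
        return EXTRACT_INACTIVE
    if not ic50_ug_ml > 0:
        raise ActivityError(f"IC50 must be positive, got {ic50_ug_ml}")
    return EXTRACT_ACTIVE if ic50_ug_ml < EXTRACT_CUTOFF_UG_ML else EXTRACT_INACTIVE


@dataclass(frozen=True)
class ActivityRecord:
    """One assay result: sample id, IC50, units, censoring flag.

    ``pic50`` is defined only for micromolar (molecule) records; extract
    records in ug/mL have no molar conversion.
    """

    sample_id: str
    ic50: float | None
    units: str  # "uM" | "ug/mL"
    censored: bool = False

    def __post_init__(self) -> None:
        if self.units not in ("uM", "ug/mL"):
            raise ActivityError(f"unknown units {self.units!r}; expected 'uM' or 'ug/mL'")
        if not self.censored:
            if self.ic50 is None or not self.ic50 > 0:
                raise ActivityError(
                    f"uncensored record {self.sample_id!r} needs a positive IC50"
                )

    @property
    def pic50(self) -> float | None:
        if self.censored or self.units != "uM":
            return None
        return ic50_um_to_pic50(self.ic50)

    def label(self, scheme: str = "ternary") -> str:
        if self.units == "ug/mL":
            return label_extract(self.ic50, censored=self.censored)
        if self.censored:
            return INACTIVE
        return label_molecule(self.ic50, scheme=scheme)
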
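"""Isotope-based derivation of leaf gas-exchange traits.

Bulk-leaf carbon isotope ratios record time-integrated photosynthetic
discrimination.  Under the simple form of the discrimination model
(no mesophyll-conductance or photorespiration terms), discrimination is an
affine function of the ratio of intercellular to ambient CO2 (Ci/Ca), which
in turn fixes the intrinsic water-use efficiency

    iWUE = A/gs = Ca/1.6 * (1 - Ci/Ca),

where the factor 1.6 is the ratio of stomatal diffusivities for water vapour
and CO2.  Oxygen isotope enrichment of leaf tissue above source water is the
standard proxy for time-integrated stomatal conductance.

All functions accept scalars or numpy arrays and broadcast like numpy
ufuncs.  Units follow field convention: isotope ratios in per mil (delta13C
vs VPDB, delta18O vs VSMOW), Ca and iWUE in micromol per mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateConstantsError, DomainError, ValidationError

__all__ = [
    "DiscriminationConstants",
    "big_delta_13C",
    "ci_over_ca",
    "iwue_from_discrimination",
    "leaf_delta13C_for_target_iwue",
    "big_delta_18O",
    "classify_pathway",
    "derive_traits",
]

#: delta13C threshold (per mil) separating C3 from C4 photosynthesis.
C4_DELTA13C_THRESHOLD = -20.0


@dataclass(frozen=True)
class DiscriminationConstants:
    """Fractionation constants of the simple discrimination model.

    Attributes
    ----------
    a : float
        Fractionation during CO2 diffusion through stomata, per mil
        (default 4.4).
    b : float
        Fractionation during fixation by Rubisco, per mil (default 27.0).
    diffusion_ratio : float
        Ratio of stomatal conductance for water vapour to that for CO2
        (fixed at 1.6 for all practical purposes).
    """

    a: float = 4.4
    b: float = 27.0
    diffusion_ratio: float = 1.6

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.diffusion_ratio > 0):
            raise ValidationError("discrimination constants must be strictly positive")
        if not self.a < self.b:
            raise DegenerateConstantsError(
                f"require a < b, got a={self.a}, b={self.b}"
            )


DEFAULT_CONSTANTS = DiscriminationConstants()


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite value in field '{name}'")
    return arr


def big_delta_13C(delta13C_air, delta13C_leaf):
    """Photosynthetic carbon isotope discrimination, per mil.

    Delta13C = (delta13C_air - delta13C_leaf) / (1 + delta13C_leaf/1000).
    """
    da = _check_finite("delta13C_air", delta13C_air)
    dl = _check_finite("delta13C_leaf", delta13C_leaf)
    if np.any(dl <= -1000.0):
        raise ValidationError("delta13C_leaf must exceed -1000 per mil")
    out = (da - dl) / (1.0 + dl / 1000.0)
    return out if out.ndim else float(out)


def ci_over_ca(big_delta13C, constants: DiscriminationConstants = DEFAULT_CONSTANTS):
    """Ratio of intercellular to ambient CO2 implied by discrimination.

    Ci/Ca = (Delta13C - a) / (b - a).  Values outside [0, 1] are returned
    as computed; flagging is the caller's responsibility (see
    :func:`derive_traits`).
    """
    d = _check_finite("big_delta13C", big_delta13C)
    if constants.a == constants.b:  # defensive; constructor forbids it
        raise DegenerateConstantsError("a == b leaves Ci/Ca undefined")
    out = (d - constants.a) / (constants.b - constants.a)
    return out if out.ndim else float(out)


def iwue_from_discrimination(
    big_delta13C, Ca, constants: DiscriminationConstants = DEFAULT_CONSTANTS
):
    """Time-integrated intrinsic water-use efficiency, micromol per mol.

    iWUE = Ca/1.6 * [1 - (Delta13C - a)/(b - a)].  Affine and strictly
    decreasing in Delta13C with slope -Ca / (1.6 (b - a)).
    """
    ca = _check_finite("Ca", Ca)
    if np.any(ca <= 0):
        raise ValidationError("Ca must be strictly positive")
    ratio = ci_over_ca(big_delta13C, constants)
    out = ca / constants.diffusion_ratio * (1.0 - np.asarray(ratio))
    return out if out.ndim else float(out)


def leaf_delta13C_for_target_iwue(
    iwue, Ca, delta13C_air, constants: DiscriminationConstants = DEFAULT_CONSTANTS
):
    """Invert the discrimination chain: bulk-leaf delta13C giving a target iWUE.

    Exact algebraic inverse of
    :func:`big_delta_13C` -> :func:`iwue_from_discrimination`; used by the
    synthetic generator to back-calculate leaf isotope ratios from latent
    water-use-efficiency values.
    """
    w = _check_finite("iwue", iwue)
    ca = _check_finite("Ca", Ca)
    da = _check_finite("delta13C_air", delta13C_air)
    upper = ca / constants.diffusion_ratio
    if np.any(w < 0) or np.any(w > upper):
        raise DomainError("target iWUE outside attainable range [0, Ca/1.6]")
    ratio = 1.0 - constants.diffusion_ratio * w / ca
    delta = constants.a + (constants.b - constants.a) * ratio
    out = (da - delta) / (1.0 + delta / 1000.0)
    return out if out.ndim else float(out)


def big_delta_18O(delta18O_leaf, delta18O_source):
    """Oxygen isotope enrichment of leaf tissue above source water, per mil.

    Delta18O = (delta18O_leaf - delta18O_source) / (1 + delta18O_source/1000).
    Source water is taken as site precipitation, assumed to reflect soil
    water available to the plant.
    """
    dl = _check_finite("delta18O_leaf", delta18O_leaf)
    ds = _check_finite("delta18O_source", delta18O_source)
    if np.any(ds <= -1000.0):
        raise ValidationError("delta18O_source must exceed -1000 per mil")
    out = (dl - ds) / (1.0 + ds / 1000.0)
    return out if out.ndim else float(out)


def classify_pathway(delta13C_leaf):
    """Classify photosynthetic pathway from bulk-leaf delta13C.

    Returns "C3" where delta13C < -20 per mil strictly, "C4" otherwise
    (the boundary value -20.0 is assigned to C4 so the rule is total).
    """
    d = _check_finite("delta13C_leaf", delta13C_leaf)
    out = np.where(d < C4_DELTA13C_THRESHOLD, "C3", "C4")
    return out if out.ndim else str(out)


def derive_traits(
    leaf_samples: pd.DataFrame,
    sites: pd.DataFrame,
    constants: DiscriminationConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Append derived isotope traits to a leaf-sample table.

    Parameters
    ----------
    leaf_samples : DataFrame
        One row per species-at-site record with columns ``species_id``,
        ``site_id``, ``delta13C_leaf``, ``delta18O_leaf``, ``SLA``,
        ``N_area``.
    sites : DataFrame
        Per-site covariates with columns ``site_id``, ``Ca``,
        ``delta13C_air``, ``delta18O_source`` (other site columns are
        carried along untouched elsewhere in the pipeline).

    Returns
    -------
    DataFrame
        Copy of ``leaf_samples`` with ``big_delta13C``, ``ci_ca``, ``iWUE``,
        ``big_delta18O``, ``pathway`` and a semicolon-separated ``flags``
        column.  Records whose discrimination falls outside [a, b] (Ci/Ca
        outside [0, 1]) are flagged ``ci_ca_out_of_range`` but retained.
    """
    required_site = {"site_id", "Ca", "delta13C_air", "delta18O_source"}
    missing = required_site - set(sites.columns)
    if missing:
        raise ValidationError(f"site table missing columns: {sorted(missing)}")
    out = leaf_samples.merge(
        sites[["site_id", "Ca", "delta13C_air", "delta18O_source"]],
        on="site_id",
        how="left",
        validate="many_to_one",
    )
    if out["Ca"].isna().any():
        orphans = sorted(out.loc[out["Ca"].isna(), "site_id"].unique())
        raise ValidationError(f"leaf samples reference unknown site_ids: {orphans}")

    out["big_delta13C"] = big_delta_13C(out["delta13C_air"], out["delta13C_leaf"])
    out["ci_ca"] = ci_over_ca(out["big_delta13C"].to_numpy(), constants)
    out["iWUE"] = iwue_from_discrimination(
        out["big_delta13C"].to_numpy(), out["Ca"].to_numpy(), constants
    )
    out["big_delta18O"] = big_delta_18O(out["delta18O_leaf"], out["delta18O_source"])
    out["pathway"] = classify_pathway(out["delta13C_leaf"].to_numpy())

    oor = (out["ci_ca"] < 0) | (out["ci_ca"] > 1)
    flags = np.where(oor, "ci_ca_out_of_range", "")
    out["flags"] = flags
    return out.drop(columns=["Ca", "delta13C_air", "delta18O_source"])
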
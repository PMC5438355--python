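"""Descriptive statistics for paired fencing/grazing soil-water experiments.

Grazing exclusion (fencing) is a standard grassland-restoration measure: a
plot is fenced against livestock and compared with an adjacent grazed
control. This module computes the percent treatment effect per variable per
site and layered soil-water storage over a profile. No inferential
statistics are attempted — typical published site tables carry no
replicate-level dispersion, so the report is descriptive only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, ValidationError


def percent_change(fenced: float, grazed: float) -> float:
    """Treatment effect as a percentage of the grazed value:
    100 * (fenced - grazed) / grazed. Rounding happens only at the reporting
    layer; raises :class:`DomainError` for a nonpositive grazed value."""
    if not grazed > 0:
        raise DomainError("percent_change requires grazed > 0")
    return 100.0 * (float(fenced) - float(grazed)) / float(grazed)


def soil_water_storage(
    layer_bounds,
    water_content,
    bulk_density=None,
    gravimetric: bool = False,
) -> float:
    """Soil-water storage (mm) over a layered profile.

    ``layer_bounds`` is a sequence of (top_cm, bottom_cm) pairs and
    ``water_content`` the per-layer water content. By default contents are
    volumetric fractions and storage is sum(thickness_mm * theta). With
    ``gravimetric=True`` contents are g water per g dry soil and a per-layer
    ``bulk_density`` (g cm^-3) converts them to volumetric (water density
    1 g cm^-3). Layers must not overlap.
    """
    bounds = [(float(t), float(b)) for t, b in layer_bounds]
    theta = np.asarray(water_content, dtype=float)
    if len(bounds) != theta.size:
        raise ValidationError("one water content per layer required")
    for top, bottom in bounds:
        if not (0.0 <= top < bottom):
            raise ValidationError(f"invalid layer bounds ({top}, {bottom})")
    for (t1, b1), (t2, b2) in zip(sorted(bounds), sorted(bounds)[1:]):
        if b1 > t2:
            raise ValidationError("overlapping soil layers")
    if np.any(theta < 0) or (not gravimetric and np.any(theta > 1)):
        raise ValidationError("volumetric water content must lie in [0, 1]")
    thickness_mm = np.array([(b - t) * 10.0 for t, b in bounds])
    if gravimetric:
        if bulk_density is None:
            raise ValidationError("gravimetric storage requires bulk_density")
        bd = np.asarray(bulk_density, dtype=float)
        if bd.size != theta.size or np.any(bd <= 0):
            raise ValidationError("one positive bulk density per layer required")
        theta = theta * bd
    return float(np.sum(thickness_mm * theta))


def site_report(measurements: pd.DataFrame) -> pd.DataFrame:
    """Percent fencing effects per (site, variable).

    ``measurements`` is long format with columns ``site, variable,
    treatment, value`` and both treatments (``fencing``, ``grazing``)
    present for every (site, variable). Returns one row per (site,
    variable) with the fencing value, grazing value and percent change.
    """
    required = {"site", "variable", "treatment", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValidationError(f"measurements missing columns: {sorted(missing)}")
    rows = []
    for (site, variable), grp in measurements.groupby(["site", "variable"], sort=True):
        by_treatment = grp.set_index("treatment")["value"]
        for treatment in ("fencing", "grazing"):
            if treatment not in by_treatment.index:
                raise DataError(
                    f"missing {treatment} value for ({site}, {variable})"
                )
        fenced = float(by_treatment["fencing"])
        grazed = float(by_treatment["grazing"])
        rows.append(
            {
                "site": site,
                "variable": variable,
                "fencing": fenced,
                "grazing": grazed,
                "percent_change": percent_change(fenced, grazed),
            }
        )
    return pd.DataFrame(rows)
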
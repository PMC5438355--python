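"""Table, configuration and report I/O.

Tables are plain CSV with a single header row and the exact columns
``year,P,T,ETp,ET,Q`` (mm per growing season, degC). Missing values are empty
cells. Reports are JSON with sections ``{config, wyc, budyko, elasticity,
attribution, recycling, soil}``; every report embeds the configuration and
seed that produced it, so a run can be reproduced from its output alone.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import TableFormatError, ValidationError
from .series import COLUMNS, CatchmentSeries, PeriodDefinition

_CONVENTIONS = ("as_printed", "standard")


def read_catchment_table(path: str | Path) -> CatchmentSeries:
    """Read a yearly catchment CSV into a validated :class:`CatchmentSeries`.

    Rows are returned sorted by year. Raises :class:`TableFormatError` for a
    missing column or a non-numeric cell (naming it), and
    :class:`ValidationError` for duplicate years or negative fluxes.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    for name in COLUMNS:
        coerced = pd.to_numeric(frame[name], errors="coerce")
        # cells that fail numeric coercion but were not empty to begin with
        bad = coerced.isna() & frame[name].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise TableFormatError(
                f"{path.name}: non-numeric value in column {name!r} at line {row}"
            )
        frame[name] = coerced
    return CatchmentSeries.from_frame(frame, sort=True)


def write_catchment_table(series: CatchmentSeries, path: str | Path) -> None:
    """Write a series as CSV at full float precision (round-trips exactly)."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclasses.dataclass
class PipelineConfig:
    """Settings for the full attribution pipeline.

    Parameters
    ----------
    periods
        Pre/post analysis periods.
    forms
        Names of elasticity f(AI) forms to use, or ``"all"`` for the bundled
        six-member ensemble.
    convention
        Elasticity denominator convention: ``"as_printed"`` uses
        ``1 - f'(AI)``, ``"standard"`` uses ``1 - f(AI)`` (the form implied
        by differentiating Q = P(1 - f)).
    detrend
        Detrend variables before water-yield-coefficient regressions.
    n_draws, subsample_size, seed
        Bootstrap settings for the catchment-parameter (omega) uncertainty:
        number of without-replacement subsamples of the pre period and their
        size. ``n_draws=0`` disables the bootstrap (plain fit is used).
    eps_r
        Regional evaporation recycling ratio (fraction of local ET returning
        as local precipitation); an external input, not computed here.
    runoff_ratio
        Streamflow/precipitation ratio used to translate recycled
        precipitation into streamflow; ``None`` means compute it from the
        post-period observations.
    yearly_budyko
        Average yearly Budyko predictions over the post period (True) rather
        than applying the curve to period-mean climate (False).
    """

    periods: PeriodDefinition = dataclasses.field(default_factory=PeriodDefinition)
    forms: tuple[str, ...] | str = "all"
    convention: str = "as_printed"
    detrend: bool = True
    n_draws: int = 5000
    subsample_size: int = 12
    seed: int = 0
    eps_r: float = 0.152
    runoff_ratio: float | None = None
    yearly_budyko: bool = True

    def __post_init__(self) -> None:
        if self.convention not in _CONVENTIONS:
            raise ValidationError(
                f"convention must be one of {_CONVENTIONS}, got {self.convention!r}"
            )
        if not (0.0 <= self.eps_r <= 1.0):
            raise ValidationError("eps_r must lie in [0, 1]")
        if self.n_draws < 0:
            raise ValidationError("n_draws must be >= 0")
        if self.subsample_size < 1:
            raise ValidationError("subsample_size must be >= 1")
        if self.runoff_ratio is not None and not (0.0 <= self.runoff_ratio <= 1.0):
            raise ValidationError("runoff_ratio must lie in [0, 1]")
        if isinstance(self.forms, list):
            self.forms = tuple(self.forms)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["periods"] = self.periods.to_dict()
        if isinstance(d["forms"], tuple):
            d["forms"] = list(d["forms"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "periods" in d and isinstance(d["periods"], dict):
            d["periods"] = PeriodDefinition(**d["periods"])
        if isinstance(d.get("forms"), list):
            d["forms"] = tuple(d["forms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _jsonify(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and dataclasses to JSON types."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonify(obj.to_dict())
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def write_report(report: Any, path: str | Path, timestamp: bool = True) -> None:
    """Write a result object (dataclass or dict) as a structured JSON report.

    The document carries every report field plus a ``created`` timestamp;
    apart from that field, identical inputs produce byte-identical files
    (keys are sorted, floats serialized at full precision).
    """
    doc = _jsonify(report)
    if not isinstance(doc, dict):
        raise ValidationError("report must serialize to a JSON object")
    if timestamp:
        doc = {"created": datetime.now(timezone.utc).isoformat(), **doc}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
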
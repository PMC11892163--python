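"""Complex-survey design description.

A :class:`SurveyDesign` names the columns of a cohort table that carry the
sampling weight, the stratum identifier and the primary sampling unit (PSU,
i.e. cluster) identifier. PSU identifiers are interpreted within stratum, so
they need only be unique inside each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class SurveyDesign:
    """Column roles for design-based estimation.

    Parameters
    ----------
    weight
        Column of strictly positive sampling weights.
    stratum
        Column of stratum identifiers.
    psu
        Column of primary-sampling-unit (cluster) identifiers, nested
        within strata.
    """

    weight: str = "weight"
    stratum: str = "stratum"
    psu: str = "psu"

    def columns(self) -> list[str]:
        return [self.weight, self.stratum, self.psu]

    def validate(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.columns() if c not in table.columns]
        if missing:
            raise InputError(f"design columns missing from table: {missing}")
        w = table[self.weight].to_numpy(dtype=float)
        if not (w > 0).all():
            raise InputError("sampling weights must be strictly positive")
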
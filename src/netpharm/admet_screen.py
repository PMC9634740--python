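"""ADMET eligibility filter on compound property tables.

Compounds qualify as candidate active components when their predicted oral
bioavailability (OB) and drug-likeness (DL) both meet inclusive minimum
thresholds; the conventional cutoffs for herbal-compound screening are
OB >= 30% and DL >= 0.18.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .io_model import Compound

logger = logging.getLogger("netpharm")

__all__ = ["screen_compounds", "OB_MIN_DEFAULT", "DL_MIN_DEFAULT"]

OB_MIN_DEFAULT = 30.0   # percent oral bioavailability
DL_MIN_DEFAULT = 0.18   # drug-likeness score


def screen_compounds(
    compounds: Sequence[Compound],
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> list[Compound]:
    """Retain exactly the compounds with ob >= ob_min and dl >= dl_min.

    Both boundaries are inclusive; input order is preserved.  The filter is
    idempotent and monotone in both thresholds.
    """
    kept = [c for c in compounds if c.ob >= ob_min and c.dl >= dl_min]
    logger.info(
        "ADMET screen (OB >= %g, DL >= %g): kept %d of %d compounds",
        ob_min, dl_min, len(kept), len(compounds),
    )
    return kept
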
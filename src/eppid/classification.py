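"""Protein classification: co-expression classes, PPID bins, interface classes.

A protein is *co-expressed* when at least half of its interaction partners
are co-expressed with it (ePPID/PPID >= 0.5), a partner-counting analogue
of the date/party-hub split.  Proteins are further binned into low, medium
and high PPID bins with the high bin ("hubs") holding about 20% of
proteins; hubs with interface counts are split into singlish- vs
multi-interface and crossed with the co-expression class into four groups.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

COEXPRESSED = "co-expressed"
NON_COEXPRESSED = "non-co-expressed"

FOUR_CLASS = {
    (NON_COEXPRESSED, "singlish"): "NC-S",
    (NON_COEXPRESSED, "multi"): "NC-M",
    (COEXPRESSED, "singlish"): "C-S",
    (COEXPRESSED, "multi"): "C-M",
}


def classify_coexpressed(ppid: int, eppid: int, ratio_threshold: float = 0.5):
    """Co-expressed iff eppid/ppid >= ratio_threshold; None when ppid == 0."""
    if ppid < 0 or eppid < 0 or eppid > ppid:
        raise ValidationError(f"need 0 <= eppid <= ppid, got eppid={eppid}, ppid={ppid}")
    if ppid == 0:
        return None
    return COEXPRESSED if eppid / ppid >= ratio_threshold else NON_COEXPRESSED


def bin_by_ppid(ppid: pd.Series, high_frac: float = 0.20) -> pd.Series:
    """Assign low/medium/high PPID bins.

    The high bin is the top ``high_frac`` of proteins by PPID, with all
    boundary ties included; the remainder is split at its median PPID, ties
    going to the medium bin.  Deterministic by construction.
    """
    if len(ppid) < 5:
        raise ValidationError("need at least 5 proteins to bin")
    if not 0 < high_frac < 1:
        raise ValidationError("high_frac must be in (0, 1)")
    values = ppid.to_numpy()
    k = max(1, round(high_frac * len(values)))
    boundary = np.sort(values)[::-1][k - 1]
    bins = pd.Series("medium", index=ppid.index, dtype=object)
    high = values >= boundary
    bins[high] = "high"
    rest = ppid[~high]
    if rest.empty:
        logger.warning("all proteins tied at the high-bin boundary; degenerate binning")
        return bins
    median = rest.median()
    bins[(~high) & (ppid < median).to_numpy()] = "low"
    return bins


def sin_hub_filter(ppid: int, min_partners: int = 5) -> bool:
    """Hub rule used in structural-interaction-network analyses: >=5 partners."""
    return ppid >= min_partners


def classify_interfaces(interface_count: int, singlish_max: int = 2) -> str:
    """Singlish- vs multi-interface: singlish iff interface_count <= singlish_max."""
    if interface_count is None or (
        isinstance(interface_count, float) and math.isnan(interface_count)
    ):
        raise ValidationError("interface count missing")
    if interface_count < 1:
        raise ValidationError("interface count must be a positive integer")
    return "singlish" if interface_count <= singlish_max else "multi"


def four_class(coexpr_class, interface_class):
    """Cross co-expression and interface classes into NC-S/NC-M/C-S/C-M."""
    if coexpr_class is None or interface_class is None:
        return None
    try:
        return FOUR_CLASS[(coexpr_class, interface_class)]
    except KeyError:
        raise ValidationError(
            f"unknown class combination ({coexpr_class!r}, {interface_class!r})"
        ) from None


def annotate(
    metrics: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
    ratio_threshold: float = 0.5,
    high_frac: float = 0.20,
    singlish_max: int = 2,
    min_partners: int = 5,
) -> pd.DataFrame:
    """Append classification columns to a metric table.

    Adds ``coexpr_class``, ``ppid_bin``, ``hub`` (member of the high bin),
    ``sin_hub`` (>= ``min_partners`` partners), and — when the attribute
    table carries ``interface_count`` — ``interface_class`` and
    ``four_class`` for SIN-style hubs.
    """
    out = metrics.copy()
    out["coexpr_class"] = [
        classify_coexpressed(p, e, ratio_threshold)
        for p, e in zip(out["ppid"], out["eppid"])
    ]
    out["ppid_bin"] = bin_by_ppid(out["ppid"], high_frac=high_frac)
    out["hub"] = out["ppid_bin"] == "high"
    out["sin_hub"] = [sin_hub_filter(p, min_partners) for p in out["ppid"]]

    if attributes is not None and "interface_count" in attributes.columns:
        iface = attributes["interface_count"].reindex(out.index)
        out["interface_class"] = [
            classify_interfaces(int(c), singlish_max)
            if (pd.notna(c) and hub) else None
            for c, hub in zip(iface, out["sin_hub"])
        ]
        out["four_class"] = [
            four_class(cc, ic) if ic is not None else None
            for cc, ic in zip(out["coexpr_class"], out["interface_class"])
        ]
    return out
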
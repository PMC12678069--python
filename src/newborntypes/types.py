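"""Six- and ten-type newborn classification.

The six types cross gestational-age class (preterm up to 36+6 weeks, term
from 37+0) with size for gestational age (SGA/AGA/LGA).  "Small" types are
any combination involving preterm and/or SGA; term+LGA is the "large" type;
term+AGA is the reference.  The ten-type secondary classification further
splits by low birthweight (<2500 g).  Two of the twelve crossings
(PT+SGA+nonLBW and T+LGA+LBW) are physiologically unexpected; they are kept
as explicit, counted buckets rather than merged away, so the partition and
collapse identities always hold exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: preterm iff gestational age <= 258 days (36+6); term iff >= 259 (37+0)
PRETERM_MAX_DAYS = 258
#: low birthweight iff < 2500 g; exactly 2500 g is nonLBW
LBW_CUTOFF_G = 2500

GA_CLASSES = ("PT", "T")
BW_CLASSES = ("LBW", "nonLBW")

TYPE6 = ("PT_SGA", "PT_AGA", "PT_LGA", "T_SGA", "T_AGA", "T_LGA")
SMALL_TYPE6 = ("PT_SGA", "PT_AGA", "PT_LGA", "T_SGA")
LARGE_TYPE6 = "T_LGA"
REFERENCE_TYPE6 = "T_AGA"

#: the ten expected gestational-age x size x birthweight types
TYPE10 = (
    "PT_SGA_LBW",
    "PT_AGA_LBW",
    "PT_AGA_nonLBW",
    "PT_LGA_LBW",
    "PT_LGA_nonLBW",
    "T_SGA_LBW",
    "T_SGA_nonLBW",
    "T_AGA_LBW",
    "T_AGA_nonLBW",
    "T_LGA_nonLBW",
)
#: crossings absent from the expected list, counted under explicit labels
UNEXPECTED_TYPE10 = ("unexpected_PT_SGA_nonLBW", "unexpected_T_LGA_LBW")
ALL_TYPE10 = TYPE10 + UNEXPECTED_TYPE10


def assign_ga_class(ga_days):
    """Preterm/term split at 258/259 days (36+6 vs 37+0 weeks)."""
    ga = np.atleast_1d(np.asarray(ga_days, dtype="int64"))
    out = np.where(ga <= PRETERM_MAX_DAYS, "PT", "T")
    return str(out[0]) if np.ndim(ga_days) == 0 else out


def assign_bw_class(bw_grams):
    """LBW/nonLBW split at 2500 g (2500 g exactly is nonLBW)."""
    bw = np.atleast_1d(np.asarray(bw_grams, dtype="int64"))
    out = np.where(bw < LBW_CUTOFF_G, "LBW", "nonLBW")
    return str(out[0]) if np.ndim(bw_grams) == 0 else out


def assign_type6(ga_days, size_class):
    """Six-type label: gestational-age class crossed with size class."""
    ga_class = assign_ga_class(ga_days)
    scalar = np.ndim(ga_days) == 0 and isinstance(size_class, str)
    ga_arr = np.atleast_1d(np.asarray(ga_class, dtype=object))
    size_arr = np.atleast_1d(np.asarray(size_class, dtype=object))
    out = np.char.add(np.char.add(ga_arr.astype(str), "_"), size_arr.astype(str))
    out = out.astype(object)
    return str(out[0]) if scalar else out


def assign_type10(type6, bw_class):
    """Ten-type label: six-type refined by LBW/nonLBW.

    The two crossings missing from the expected ten (PT+SGA+nonLBW and
    T+LGA+LBW) receive ``unexpected_`` labels and are never silently merged.
    """
    scalar = isinstance(type6, str)
    t6 = np.atleast_1d(np.asarray(type6, dtype=object))
    bwc = np.atleast_1d(np.asarray(bw_class, dtype=object))
    out = np.char.add(np.char.add(t6.astype(str), "_"), bwc.astype(str)).astype(object)
    for label in UNEXPECTED_TYPE10:
        out[out == label.removeprefix("unexpected_")] = label
    return str(out[0]) if scalar else out


def classify_records(records: pd.DataFrame, standard) -> pd.DataFrame:
    """Annotate cleaned records with all classification dimensions.

    Adds ``ga_class``, ``size_class``, ``bw_class``, ``type6``, ``type10``
    and the ``small``/``large`` composite indicators.  Records must have
    passed the exclusion cascade (no missing values, gestational age within
    the standard's range).
    """
    typed = records.copy()
    ga = typed["ga_days"].astype("int64").to_numpy()
    bw = typed["bw_grams"].astype("int64").to_numpy()
    sex = typed["sex"].to_numpy(dtype=object)
    size = standard.classify(bw, sex, ga)
    typed["ga_class"] = assign_ga_class(ga)
    typed["size_class"] = size
    typed["bw_class"] = assign_bw_class(bw)
    typed["type6"] = assign_type6(ga, size)
    typed["type10"] = assign_type10(
        typed["type6"].to_numpy(dtype=object), typed["bw_class"].to_numpy(dtype=object)
    )
    typed["small"] = typed["type6"].isin(SMALL_TYPE6)
    typed["large"] = typed["type6"] == LARGE_TYPE6
    return typed


def type_counts(
    typed: pd.DataFrame,
    by: tuple[str, ...] = ("country", "year"),
    which: str = "type6",
) -> pd.DataFrame:
    """Counts per type per group, one row per group, one column per type.

    Every type level appears as a column (zero-filled), plus ``n`` with the
    group size, so counts always sum to the group size exactly.
    """
    levels = TYPE6 if which == "type6" else ALL_TYPE10
    counts = (
        typed.groupby(list(by))[which]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=levels, fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts["n"] = counts[list(levels)].sum(axis=1)
    return counts


def collapse_type10(counts10: pd.DataFrame) -> pd.DataFrame:
    """Collapse a ten-type count table back to six types exactly.

    Unexpected buckets fold into the six-type cell they refine, so the
    refinement identity ``collapse(type10) == type6`` holds by construction.
    """
    group_cols = [c for c in counts10.columns if c not in ALL_TYPE10 + ("n",)]
    out = counts10[group_cols].copy()
    for t6 in TYPE6:
        members = [
            t10
            for t10 in ALL_TYPE10
            if t10.removeprefix("unexpected_").startswith(t6 + "_")
        ]
        out[t6] = counts10[members].sum(axis=1)
    out["n"] = out[list(TYPE6)].sum(axis=1)
    return out
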
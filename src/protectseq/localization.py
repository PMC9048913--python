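"""Localization inference from protection-assay contrast patterns.

Each feature's behaviour across the three contrasts — RNase A vs control
(R_vs_C), trypsin + RNase A vs control (TR_vs_C) and trypsin + RNase A vs
RNase A (TR_vs_R) — is reduced to a direction triple (up / down / ns at
padj <= alpha) and translated to a physical localization call:

* enrichment only after trypsin (ns, up, up): protected regardless of
  protease, i.e. inside vesicles;
* enrichment after RNase alone *and* after trypsin (up, up, up-or-ns): present
  both inside vesicles and outside in protein complexes;
* enrichment after RNase alone but depletion after trypsin (up, down, down):
  outside vesicles, shielded by RNA-binding proteins;
* depletion already after RNase alone (down, down, *): outside vesicles and
  unprotected;
* anything else: ambiguous.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

DIRECTIONS = ("up", "down", "ns")
CALLS = ("inside_EV", "inside_and_outside_protected", "outside_protected",
         "outside_unprotected", "ambiguous")
CONTRAST_ORDER = ("R_vs_C", "TR_vs_C", "TR_vs_R")

DEFAULT_ALPHA = 0.05  # BH-adjusted significance for direction calls
DEFAULT_TAU = 0.20    # relative-change threshold for category shares


def _call_for(pattern: tuple[str, str, str]) -> str:
    r_c, tr_c, tr_r = pattern
    if (r_c, tr_c, tr_r) == ("ns", "up", "up"):
        return "inside_EV"
    if r_c == "up" and tr_c == "up" and tr_r in ("up", "ns"):
        return "inside_and_outside_protected"
    if (r_c, tr_c, tr_r) == ("up", "down", "down"):
        return "outside_protected"
    if r_c == "down" and tr_c == "down":
        return "outside_unprotected"
    return "ambiguous"


#: total decision table over all 27 direction triples
DECISION_TABLE: dict[tuple[str, str, str], str] = {
    pat: _call_for(pat) for pat in itertools.product(DIRECTIONS, repeat=3)
}


def filter_by_rpm(
    rpm_table: pd.DataFrame,
    threshold: float,
    mode: str = "any_sample",
    comparator: str = ">",
) -> pd.Index:
    """Detection filter on an RPM table.

    ``comparator`` is ``">"`` for the strict more-than-one-RPM miRNA filter
    and ``">="`` for the five-RPM minimum cut-off used for tasiRNAs.
    """
    if threshold < 0:
        raise ValueError("RPM threshold must be non-negative")
    if comparator == ">":
        hit = rpm_table > threshold
    elif comparator == ">=":
        hit = rpm_table >= threshold
    else:
        raise ValueError("comparator must be '>' or '>='")
    if mode == "any_sample":
        keep = hit.any(axis=1)
    elif mode == "all_samples":
        keep = hit.all(axis=1)
    else:
        raise ValueError("mode must be 'any_sample' or 'all_samples'")
    return rpm_table.index[keep]


def classify_feature(pattern: tuple[str, str, str] | dict) -> str:
    """Localization call for one (R_vs_C, TR_vs_C, TR_vs_R) direction triple."""
    if isinstance(pattern, dict):
        missing = [c for c in CONTRAST_ORDER if c not in pattern]
        if missing:
            raise ValueError(f"missing contrasts: {missing}")
        pattern = tuple(pattern[c] for c in CONTRAST_ORDER)
    pattern = tuple(pattern)
    if pattern not in DECISION_TABLE:
        raise ValueError(f"invalid pattern {pattern!r}")
    return DECISION_TABLE[pattern]


def directions(contrast: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """up / down / ns per feature; ns whenever padj is NA or above alpha."""
    sig = contrast["padj"].le(alpha).fillna(False)
    out = pd.Series("ns", index=contrast.index)
    out[sig & (contrast["log2FC"] > 0)] = "up"
    out[sig & (contrast["log2FC"] < 0)] = "down"
    return out


def classify_table(
    contrasts: dict[str, pd.DataFrame],
    alpha: float = DEFAULT_ALPHA,
    features: pd.Index | None = None,
) -> pd.DataFrame:
    """Localization calls for every feature from the three contrast tables."""
    missing = [c for c in CONTRAST_ORDER if c not in contrasts]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    dirs = {c: directions(contrasts[c], alpha) for c in CONTRAST_ORDER}
    idx = contrasts[CONTRAST_ORDER[0]].index if features is None else pd.Index(features)
    rows = []
    for feat in idx:
        pat = tuple(dirs[c].get(feat, "ns") for c in CONTRAST_ORDER)
        rows.append((feat, *pat, "/".join(pat), DECISION_TABLE[pat]))
    return pd.DataFrame(rows, columns=["feature_id", *CONTRAST_ORDER, "pattern", "call"]) \
        .set_index("feature_id")


def category_protection_profile(
    category_means: pd.DataFrame,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Category-level protection calls from mean abundance shares per treatment.

    ``category_means`` is category x treatment (columns C, R, TR; mean RPM or
    shares). Shares up in R vs C and down in TR vs R indicate protein
    protection outside vesicles; the opposite movement is the tRNA-like mixed
    pattern (naked outside plus vesicle cargo); a share up in TR vs C marks
    vesicle enrichment; anything else is stable. A relative change of at least
    ``tau`` counts as movement.
    """
    for t in ("C", "R", "TR"):
        if t not in category_means.columns:
            raise ValueError(f"missing treatment column {t!r}")
    shares = category_means / category_means.sum(axis=0)

    def updown(b, a):
        if b >= a * (1 + tau):
            return "up"
        if b <= a * (1 - tau):
            return "down"
        return "ns"

    rows = []
    for cat, row in shares.iterrows():
        r_c = updown(row["R"], row["C"])
        tr_r = updown(row["TR"], row["R"])
        tr_c = updown(row["TR"], row["C"])
        if r_c == "up" and tr_r == "down":
            call = "outside_protected"
        elif r_c == "down" and tr_r == "up":
            call = "outside_mixed_naked_and_insideEV"
        elif tr_c == "up":
            call = "inside_EV"
        else:
            call = "stable"
        rows.append((cat, row["C"], row["R"], row["TR"], r_c, tr_r, tr_c, call))
    return pd.DataFrame(rows, columns=["category", "share_C", "share_R", "share_TR",
                                       "R_vs_C", "TR_vs_R", "TR_vs_C", "call"]) \
        .set_index("category")


def recover_localization(
    calls: pd.Series,
    truth: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Confusion matrix (truth x call) and per-class recall on shared features."""
    shared = calls.index.intersection(truth.index)
    confusion = pd.crosstab(truth.loc[shared], calls.loc[shared],
                            rownames=["truth"], colnames=["call"])
    recall = pd.Series(
        {cls: (confusion.loc[cls, cls] / confusion.loc[cls].sum()
               if cls in confusion.index and cls in confusion.columns
               and confusion.loc[cls].sum() > 0 else np.nan)
         for cls in confusion.index},
        name="recall",
    )
    return confusion, recall
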
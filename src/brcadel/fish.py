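"""FISH spot-count deletion calling and exact 2x2 diagnostic statistics.

Each nucleus is scored for green (pericentromeric) and red (deletion-probe)
spots.  Within a sample/chromosome the modal green count defines the ploidy
reference; the deletion percentage is the share of modal-green nuclei with
fewer red spots than the modal count (nuclei with single green and single
red spots count as deleted monosomy when the modal count is 1).  A sample is
called "loss" when the percentage is >= 50 and "other" below; the screen is
evaluated against mutation status by a two-sided Fisher exact test
(probability-ordering definition, computed with exact integer arithmetic)
and by sensitivity/specificity.
"""
from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from .containers import CASE_LABEL, CONTROL_LABEL

__all__ = ["modal_green", "deletion_percentage", "call_deletion",
           "summarize_fish", "calls_from_percentages", "build_contingency",
           "fisher_exact_two_sided", "diagnostic_metrics"]

DELETION_THRESHOLD = 50.0


def modal_green(greens) -> int:
    """Most frequent green spot count; ties broken toward the larger count."""
    greens = np.asarray(greens, dtype=int)
    if greens.size == 0:
        raise ValueError("no nuclei scored")
    if (greens < 0).any():
        raise ValueError("spot counts must be >= 0")
    counts = np.bincount(greens)
    best = counts.max()
    return int(np.flatnonzero(counts == best)[-1])


def deletion_percentage(green, red, denominator: str = "modal") -> float:
    """Percentage of nuclei scored as deleted.

    With ``denominator="modal"`` (the default reading of the scoring rule)
    only nuclei carrying the modal green count are considered: those with
    red < modal, or with single green and single red spots when the modal
    count is 1, count as deleted.  ``denominator="all"`` uses every nucleus
    as the denominator instead.
    """
    green = np.asarray(green, dtype=int)
    red = np.asarray(red, dtype=int)
    if green.shape != red.shape or green.size == 0:
        raise ValueError("green and red must be equal-length, non-empty")
    if (red < 0).any():
        raise ValueError("spot counts must be >= 0")
    modal = modal_green(green)
    is_modal = green == modal
    deleted = is_modal & ((red < modal) | ((green == 1) & (red == 1)))
    if denominator == "modal":
        denom = int(is_modal.sum())
    elif denominator == "all":
        denom = green.size
    else:
        raise ValueError("denominator must be 'modal' or 'all'")
    if denom == 0:
        raise ValueError("no nuclei in the denominator")
    return 100.0 * int(deleted.sum()) / denom


def call_deletion(percent: float, threshold: float = DELETION_THRESHOLD) -> str:
    """'loss' when the deletion percentage is >= threshold, else 'other'."""
    return "loss" if percent >= threshold else "other"


def summarize_fish(counts: pd.DataFrame, labels: pd.Series | None = None,
                   threshold: float = DELETION_THRESHOLD,
                   denominator: str = "modal") -> pd.DataFrame:
    """Per-sample deletion percentages and calls from nucleus spot counts.

    ``counts`` has columns sample_id, chromosome, green, red (one row per
    nucleus).  Returns one row per sample with ``pct_<chrom>`` and
    ``call_<chrom>`` columns plus a ``combined_call`` that is "loss" only
    when every scored chromosome is lost.
    """
    required = {"sample_id", "chromosome", "green", "red"}
    if missing := required - set(counts.columns):
        raise ValueError(f"counts missing columns: {sorted(missing)}")
    chroms = sorted(counts["chromosome"].astype(str).unique())
    rows = {}
    for (sample, chrom), grp in counts.groupby(["sample_id", "chromosome"], sort=False):
        pct = deletion_percentage(grp["green"], grp["red"], denominator=denominator)
        rows.setdefault(sample, {})[str(chrom)] = pct
    records = []
    for sample, pcts in rows.items():
        rec = {"sample_id": sample}
        calls = []
        for chrom in chroms:
            pct = pcts.get(chrom)
            rec[f"pct_{chrom}"] = pct
            call = call_deletion(pct, threshold) if pct is not None else "other"
            rec[f"call_{chrom}"] = call
            calls.append(call)
        rec["combined_call"] = "loss" if calls and all(c == "loss" for c in calls) else "other"
        records.append(rec)
    out = pd.DataFrame(records).set_index("sample_id")
    if labels is not None:
        out.insert(0, "label", pd.Series(labels).loc[out.index])
    return out


def calls_from_percentages(percentages: pd.DataFrame, labels: pd.Series | None = None,
                           threshold: float = DELETION_THRESHOLD) -> pd.DataFrame:
    """Same call table as :func:`summarize_fish`, from per-chromosome
    deletion percentages (one row per sample, one column per chromosome)."""
    out = pd.DataFrame(index=percentages.index)
    calls = []
    for chrom in percentages.columns:
        out[f"pct_{chrom}"] = percentages[chrom].astype(float)
        out[f"call_{chrom}"] = [call_deletion(p, threshold) for p in out[f"pct_{chrom}"]]
        calls.append(out[f"call_{chrom}"])
    combined = np.all(np.vstack([c == "loss" for c in calls]), axis=0)
    out["combined_call"] = np.where(combined, "loss", "other")
    if labels is not None:
        out.insert(0, "label", pd.Series(labels).loc[out.index])
    return out


def build_contingency(call_table: pd.DataFrame, scope: str = "both",
                      case_label: str = CASE_LABEL,
                      control_label: str = CONTROL_LABEL) -> np.ndarray:
    """2x2 table rows (case, control) x columns (other, loss).

    ``scope`` is "both" (combined call: loss on every chromosome) or a
    chromosome name (uses that chromosome's call column).
    """
    if len(call_table) == 0:
        raise ValueError("empty cohort")
    col = "combined_call" if scope == "both" else f"call_{scope}"
    if col not in call_table.columns:
        raise ValueError(f"no call column for scope {scope!r}")
    labels = call_table["label"]
    table = np.zeros((2, 2), dtype=int)
    for i, lab in enumerate((case_label, control_label)):
        calls = call_table.loc[labels == lab, col]
        table[i, 0] = int((calls == "other").sum())
        table[i, 1] = int((calls == "loss").sum())
    return table


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value by full lattice enumeration.

    With margins fixed, sums the hypergeometric probability of every 2x2
    table whose probability does not exceed the observed one.  Probabilities
    are compared as exact integers (numerators over the common denominator
    C(n, c1)), so ties are handled exactly.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n == 0:
        return 1.0
    a_obs = int(t[0, 0])
    obs_num = comb(r1, a_obs) * comb(r2, c1 - a_obs)
    total = comb(n, c1)
    p_num = 0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, a) * comb(r2, c1 - a)
        if num <= obs_num:
            p_num += num
    return p_num / total


def diagnostic_metrics(table) -> tuple[float, float]:
    """(sensitivity, specificity) as exact fractions in [0, 1].

    Rows (case, control) x columns (other, loss): sensitivity is the share
    of cases called loss, specificity the share of controls called other.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    case_total, control_total = t[0].sum(), t[1].sum()
    if case_total == 0 or control_total == 0:
        raise ValueError("both groups must be non-empty")
    return float(t[0, 1] / case_total), float(t[1, 0] / control_total)
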
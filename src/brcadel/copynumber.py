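"""Gain/loss calling on ordered probe log2 ratios and BAF imbalance flagging.

Probes are BED-like records (chromosome, start, end, probe_id, log2ratio)
sorted by genomic position, 0-based half-open.  Calls are threshold-based
(defaults +/-0.25 log2, conventional BAC-array practice); cumulative
aberration frequencies summarize per-group recurrence; the common region of
overlap is the set of maximal probe runs lost in 100% of case samples.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["call_probes", "cumulative_frequency", "common_region_overlap",
           "baf_imbalance", "plot_frequency"]

LOSS_THRESHOLD = -0.25
GAIN_THRESHOLD = 0.25


def _sorted_probes(profile: pd.DataFrame) -> pd.DataFrame:
    required = {"chromosome", "start", "end", "probe_id", "log2ratio"}
    missing = required - set(profile.columns)
    if missing:
        raise ValueError(f"probe profile missing columns: {sorted(missing)}")
    if not np.isfinite(profile["log2ratio"].to_numpy(dtype=float)).all():
        raise ValueError("log2 ratios must be finite")
    return profile.sort_values(["chromosome", "start"], kind="stable")


def call_probes(profile: pd.DataFrame, loss_thr: float = LOSS_THRESHOLD,
                gain_thr: float = GAIN_THRESHOLD) -> pd.DataFrame:
    """Add a ``call`` column: loss if log2ratio <= loss_thr, gain if >= gain_thr."""
    if not loss_thr < gain_thr:
        raise ValueError("loss threshold must be below gain threshold")
    out = _sorted_probes(profile).copy()
    ratio = out["log2ratio"].to_numpy(dtype=float)
    call = np.where(ratio <= loss_thr, "loss",
                    np.where(ratio >= gain_thr, "gain", "neutral"))
    out["call"] = call
    return out


def _aligned_calls(profiles: list[pd.DataFrame]) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack per-sample calls on a shared probe grid -> (probe frame, calls matrix)."""
    if not profiles:
        raise ValueError("need at least one probe profile")
    base = _sorted_probes(profiles[0])[["chromosome", "start", "end", "probe_id"]]
    calls = []
    for prof in profiles:
        prof = _sorted_probes(prof)
        if not np.array_equal(prof["probe_id"].to_numpy(), base["probe_id"].to_numpy()):
            raise ValueError("profiles must share the same probe grid")
        if "call" not in prof.columns:
            raise ValueError("profiles must be called first (call_probes)")
        calls.append(prof["call"].to_numpy())
    return base.reset_index(drop=True), np.vstack(calls)


def cumulative_frequency(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-probe fraction of samples called gain / loss within one group.

    Loss is conventionally plotted as a negative frequency; the returned
    frame keeps both fractions in [0, 1] (columns ``frac_gain`` and
    ``frac_loss``).
    """
    base, calls = _aligned_calls(profiles)
    out = base.copy()
    out["frac_gain"] = (calls == "gain").mean(axis=0)
    out["frac_loss"] = (calls == "loss").mean(axis=0)
    return out


def _runs_to_regions(base: pd.DataFrame, mask: np.ndarray,
                     gap_tolerance: int = 0) -> pd.DataFrame:
    """Merge maximal runs of True probes into genomic intervals per chromosome."""
    regions = []
    for chrom, grp in base.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        m = mask[idx]
        i = 0
        while i < len(m):
            if not m[i]:
                i += 1
                continue
            j = i
            gap = 0
            end = i
            while j + 1 < len(m):
                if m[j + 1]:
                    j += 1
                    end = j
                    gap = 0
                elif gap < gap_tolerance:
                    j += 1
                    gap += 1
                else:
                    break
            regions.append({
                "chromosome": chrom,
                "start": int(grp.loc[idx[i], "start"]),
                "end": int(grp.loc[idx[end], "end"]),
            })
            i = end + 1
    return pd.DataFrame(regions, columns=["chromosome", "start", "end"])


def common_region_overlap(profiles: list[pd.DataFrame],
                          gap_tolerance: int = 0) -> pd.DataFrame:
    """Regions lost in 100% of the supplied (case) samples.

    Maximal runs of consecutive probes called loss in every sample, merged
    into intervals spanning the outermost probe bounds of each run.  A
    single non-loss probe breaks a run unless ``gap_tolerance`` > 0.
    """
    base, calls = _aligned_calls(profiles)
    all_loss = (calls == "loss").all(axis=0)
    return _runs_to_regions(base, all_loss, gap_tolerance=gap_tolerance)


def baf_imbalance(track: pd.DataFrame, het_band: tuple[float, float] = (0.3, 0.7),
                  window: int = 25, dev_thr: float = 0.15) -> pd.DataFrame:
    """Flag windows of heterozygous SNPs with allelic imbalance.

    Heterozygous SNPs are taken from the ``is_het`` column when present (a
    paired-normal genotype); otherwise SNPs whose BAF falls inside
    ``het_band`` are used, which under-calls hets inside strong imbalance.
    Non-overlapping windows of ``window`` consecutive hets per chromosome are
    flagged when the mean |BAF - 0.5| exceeds ``dev_thr``; adjacent flagged
    windows are merged.  A window larger than the chromosome's het track
    yields a single whole-track decision.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if "is_het" in track.columns:
        hets = track[track["is_het"].astype(bool)]
    else:
        lo, hi = het_band
        hets = track[(track["baf"] >= lo) & (track["baf"] <= hi)]
    hets = hets.sort_values(["chromosome", "pos"], kind="stable")
    regions = []
    for chrom, grp in hets.groupby("chromosome", sort=False):
        dev = (grp["baf"] - 0.5).abs().to_numpy()
        pos = grp["pos"].to_numpy()
        n = len(grp)
        if n == 0:
            continue
        starts = list(range(0, n, window)) if n > window else [0]
        flagged = []
        for s in starts:
            e = min(s + window, n)
            if dev[s:e].mean() > dev_thr:
                flagged.append((s, e))
        # merge adjacent flagged windows
        for s, e in flagged:
            if regions and regions[-1]["chromosome"] == chrom and \
                    regions[-1]["_stop"] == s:
                regions[-1]["end"] = int(pos[e - 1])
                regions[-1]["_stop"] = e
            else:
                regions.append({"chromosome": chrom, "start": int(pos[s]),
                                "end": int(pos[e - 1]), "_stop": e})
    out = pd.DataFrame(regions, columns=["chromosome", "start", "end", "_stop"])
    return out.drop(columns="_stop")


def plot_frequency(track: pd.DataFrame, ax=None):
    """Signed cumulative gain/loss frequency per probe index (loss negative)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(track))
    ax.vlines(x, 0, track["frac_gain"], color="tab:red", label="gain")
    ax.vlines(x, -track["frac_loss"], 0, color="tab:green", label="loss")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("probe index (genome order)")
    ax.set_ylabel("fraction of samples")
    ax.legend(loc="upper right", frameon=False)
    return ax
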
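"""Ribosome pause-site calling and condition-response classification.

A pause site is a codon whose normalized footprint occupancy exceeds ten
times the mRNA's average over the retained window (everything except the
first 15 and last 5 codons). Across a depletion experiment a site is
"sustained" when it pauses in both conditions; "resolved" when it pauses
only in control and its occupancy drop exceeds ten times the mRNA's
average delta decrease; and "induced" when it pauses only in knockdown
and its rise exceeds ten times the average delta increase. Conditioning
resolved/induced on a change in pause membership keeps a strong pause
whose height merely fluctuates (count noise at a tall peak scales with
the peak) from masquerading as a condition response.

Detection runs on replicate-summed normalized profiles per condition;
classification deltas are replicate means, matching how the occupancy
delta is defined. The called codon is taken as the P-site codon (counts
were assigned at the 12 nt P-site offset), so E = called - 1 and
A = called + 1.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .codons import AMINO_ACIDS, GENETIC_CODE
from .core_io import InputError, Transcript
from .ribo import ProfileSet

PAUSE_CLASSES = ("sustained", "resolved", "induced")
CONTEXT_POSITIONS = ("E-3", "E-2", "E-1", "E", "P", "A", "A+1", "A+2", "A+3")


def retained_indices(n_codons: int, exclusion: tuple[int, int] = (15, 5)) -> np.ndarray:
    """Codon indices outside the 5' and 3' exclusion zones."""
    lo, hi = exclusion
    return np.arange(lo, n_codons - hi)


def detect_pauses(
    profile: np.ndarray,
    exclusion: tuple[int, int] = (15, 5),
    fold: float = 10.0,
    nonzero_only: bool = False,
) -> np.ndarray:
    """Codon indices whose occupancy is strictly above fold x the mRNA average.

    The average runs over all retained positions, zeros and the candidate
    included (set ``nonzero_only`` to average over nonzero positions
    instead). An mRNA shorter than the exclusion zones, or with an
    all-zero retained window, yields no sites.
    """
    profile = np.asarray(profile, dtype=float)
    idx = retained_indices(len(profile), exclusion)
    if idx.size == 0:
        return np.array([], dtype=int)
    window = profile[idx]
    base = window[window > 0] if nonzero_only else window
    if base.size == 0 or base.mean() == 0:
        return np.array([], dtype=int)
    return idx[window > fold * base.mean()]


def _replicate_stack(profiles: ProfileSet, tid: str, cond: str) -> np.ndarray:
    reps = profiles.replicates(cond)
    return np.vstack([profiles.get(tid, cond, r) for r in reps])


def classify_pause_change(
    profiles: ProfileSet,
    ctrl_label: str = "ctrl",
    kd_label: str = "kd",
    exclusion: tuple[int, int] = (15, 5),
    fold: float = 10.0,
    nonzero_only: bool = False,
) -> pd.DataFrame:
    """Call pause sites in both conditions and classify their response.

    Expects a ProfileSet of normalized occupancies holding both
    conditions. Returns one row per classified site: transcript_id,
    codon_index, peak_ctrl, peak_kd, delta, pause_class. Sites pausing in
    only one condition and failing the matching delta rule are not
    classifiable and are omitted.
    """
    if profiles.replicates(ctrl_label) != profiles.replicates(kd_label):
        raise InputError("replicate labels differ between conditions")
    rows = []
    for tid in profiles.transcripts():
        ctrl_stack = _replicate_stack(profiles, tid, ctrl_label)
        kd_stack = _replicate_stack(profiles, tid, kd_label)
        ctrl_mean = ctrl_stack.mean(axis=0)
        kd_mean = kd_stack.mean(axis=0)
        delta = kd_mean - ctrl_mean

        paused_ctrl = set(detect_pauses(ctrl_stack.sum(axis=0), exclusion, fold, nonzero_only))
        paused_kd = set(detect_pauses(kd_stack.sum(axis=0), exclusion, fold, nonzero_only))
        if not paused_ctrl and not paused_kd:
            continue

        idx = retained_indices(len(delta), exclusion)
        d = delta[idx]
        neg, pos = d[d < 0], d[d > 0]
        # average delta decrease/increase across the mRNA: the negative
        # (resp. positive) part averaged over all retained positions, so a
        # single collapsing peak on an otherwise flat mRNA still dominates
        # its own mRNA-wide average
        avg_dec = float(np.abs(neg).sum() / idx.size) if neg.size else np.nan
        avg_inc = float(pos.sum() / idx.size) if pos.size else np.nan

        for codon in sorted(paused_ctrl | paused_kd):
            dv = delta[codon]
            label = None
            if codon in paused_ctrl and codon in paused_kd:
                # present in both conditions: the pause persists
                label = "sustained"
            elif codon in paused_ctrl and neg.size and -dv > fold * avg_dec:
                label = "resolved"
            elif codon in paused_kd and pos.size and dv > fold * avg_inc:
                label = "induced"
            if label is None:
                continue
            rows.append(
                {
                    "transcript_id": tid,
                    "codon_index": int(codon),
                    "peak_ctrl": float(ctrl_mean[codon]),
                    "peak_kd": float(kd_mean[codon]),
                    "delta": float(dv),
                    "pause_class": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "codon_index", "peak_ctrl", "peak_kd", "delta", "pause_class"],
    )


def mrna_class_summary(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-mRNA Venn summary: the set of pause classes present, and whether
    the mRNA carries distinctly one class."""
    rows = []
    for tid, grp in sites.groupby("transcript_id"):
        classes = sorted(set(grp["pause_class"]))
        rows.append(
            {
                "transcript_id": tid,
                "classes": "+".join(classes),
                "n_sites": len(grp),
                "distinct": len(classes) == 1,
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "classes", "n_sites", "distinct"])


def pause_context_matrix(
    sites: pd.DataFrame, transcripts: Mapping[str, Transcript]
) -> tuple[pd.DataFrame, int]:
    """Amino-acid frequencies around paused ribosomes.

    Nine codon positions spanning three codons upstream of the E site
    through three codons downstream of the A site, with the called codon
    at the P site. Sites whose window leaves the sense CDS (including
    hitting the stop codon) are dropped; the count of dropped sites is
    returned alongside the position x amino-acid matrix (columns sum
    to 1).
    """
    if sites.empty:
        raise InputError("no pause sites")
    counts = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(CONTEXT_POSITIONS))
    dropped = 0
    offsets = range(-4, 5)  # relative to the called (P-site) codon
    for row in sites.itertuples(index=False):
        t = transcripts[row.transcript_id]
        codons = t.codons()
        window = []
        for off in offsets:
            i = row.codon_index + off
            aa = GENETIC_CODE.get(codons[i]) if 0 <= i < len(codons) else None
            window.append(aa)
        if any(aa is None for aa in window):
            dropped += 1
            continue
        for pos_label, aa in zip(CONTEXT_POSITIONS, window):
            counts.loc[aa, pos_label] += 1
    totals = counts.sum(axis=0)
    if (totals == 0).all():
        raise InputError("all pause sites dropped: windows leave the CDS")
    freq = counts / totals.replace(0, np.nan)
    return freq, dropped
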
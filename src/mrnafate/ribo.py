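"""Ribosome-profiling occupancy, metagene deltas, and translational efficiency.

Works from per-transcript per-codon P-site count tables (not raw reads).
Footprint read lengths are retained by their dominant-frame fraction;
E/P/A-site nucleotide offsets from the read 5' end default to 9/12/15 nt.
Translational efficiency is log2FC RPF - log2FC RNA, with fold changes from
median-of-ratios-normalized counts and a pseudocount (a deliberately
simple, deterministic replacement for shrinkage-based differential
expression estimators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CountTable, InputError
from .seqfeat import positional_bins

DEFAULT_OFFSETS: Mapping[str, int] = {"E": 9, "P": 12, "A": 15}


@dataclass
class PositionProfile:
    transcript_id: str
    condition: str
    replicate: str
    counts: np.ndarray  # one value per codon of the CDS


class ProfileSet:
    """Per-codon count/rate vectors keyed by (transcript, condition, replicate)."""

    def __init__(self) -> None:
        self._data: dict[tuple[str, str, str], np.ndarray] = {}

    def add(self, transcript_id: str, condition: str, replicate: str, counts: np.ndarray) -> None:
        arr = np.asarray(counts, dtype=float)
        if not np.isfinite(arr).all():
            raise InputError(f"{transcript_id}: non-finite counts")
        self._data[(transcript_id, condition, replicate)] = arr

    def get(self, transcript_id: str, condition: str, replicate: str) -> np.ndarray:
        return self._data[(transcript_id, condition, replicate)]

    def __len__(self) -> int:
        return len(self._data)

    def transcripts(self) -> list[str]:
        return sorted({k[0] for k in self._data})

    def conditions(self) -> list[str]:
        return sorted({k[1] for k in self._data})

    def replicates(self, condition: str) -> list[str]:
        return sorted({k[2] for k in self._data if k[1] == condition})

    def library_size(self, condition: str, replicate: str) -> float:
        return float(
            sum(v.sum() for (t, c, r), v in self._data.items() if c == condition and r == replicate)
        )

    def transcript_totals(self, condition: str) -> pd.DataFrame:
        """Summed counts per transcript x replicate (RPF pseudo-count table)."""
        cols: dict[str, dict[str, float]] = {}
        for (tid, cond, rep), v in self._data.items():
            if cond == condition:
                cols.setdefault(rep, {})[tid] = float(v.sum())
        return pd.DataFrame(cols).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tid, cond, rep), v in sorted(self._data.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": tid,
                        "condition": cond,
                        "replicate": rep,
                        "codon_index": np.arange(len(v)),
                        "count": v,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProfileSet":
        ps = cls()
        for (tid, cond, rep), grp in frame.groupby(
            ["transcript_id", "condition", "replicate"], sort=False
        ):
            n = int(grp["codon_index"].max()) + 1
            arr = np.zeros(n)
            arr[grp["codon_index"].to_numpy()] = grp["count"].to_numpy()
            ps.add(str(tid), str(cond), str(rep), arr)
        return ps


def select_read_lengths(
    length_histogram: Mapping[int, int],
    frame_table: Mapping[int, Sequence[float]],
    threshold: float = 0.5,
) -> list[int]:
    """Retain read lengths whose dominant-frame fraction meets the threshold.

    ``frame_table`` maps read length to its (frame0, frame1, frame2) read
    fractions; lengths with no clear sub-codon periodicity are rejected.
    """
    if not length_histogram:
        raise InputError("empty read-length histogram")
    retained = []
    for length in sorted(length_histogram):
        if length_histogram[length] <= 0:
            continue
        fracs = frame_table.get(length)
        if fracs is None:
            continue
        if max(fracs) >= threshold:
            retained.append(length)
    return retained


def apply_psite_offset(
    read_starts: Iterable[int],
    cds_start: int,
    cds_len: int,
    offsets: Mapping[str, int] = DEFAULT_OFFSETS,
) -> tuple[dict[str, np.ndarray], int]:
    """Map read 5' ends to E/P/A-site nucleotide coordinates.

    Returns per-site in-CDS coordinates (transcript nt) and the number of
    site assignments that fell outside the CDS and were dropped.
    """
    for site in offsets:
        if site not in ("E", "P", "A"):
            raise InputError(f"unknown ribosomal site {site!r}")
    starts = np.asarray(list(read_starts), dtype=int)
    out: dict[str, np.ndarray] = {}
    dropped = 0
    for site, off in offsets.items():
        pos = starts + off
        in_cds = (pos >= cds_start) & (pos < cds_start + cds_len)
        dropped += int((~in_cds).sum())
        out[site] = pos[in_cds]
    return out, dropped


def codon_counts(psite_nt_positions: Iterable[int], cds_start: int, n_codons: int) -> np.ndarray:
    """Accumulate nucleotide-resolution P-site hits into per-codon counts."""
    pos = np.asarray(list(psite_nt_positions), dtype=int)
    codon_idx = (pos - cds_start) // 3
    if len(codon_idx) and (codon_idx.min() < 0 or codon_idx.max() >= n_codons):
        raise InputError("P-site position outside the CDS")
    return np.bincount(codon_idx, minlength=n_codons).astype(float)


def tpm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Transcripts per million from counts and transcript lengths (nt)."""
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        raise InputError("non-positive transcript length")
    if counts.sum() == 0:
        raise InputError("all-zero count column")
    rate = counts / lengths
    return 1e6 * rate / rate.sum()


def normalized_occupancy(
    counts: np.ndarray, library_size: float, rna_tpm: float
) -> np.ndarray:
    """Per-codon occupancy rate: library-size-scaled counts over mRNA abundance."""
    if library_size <= 0:
        raise InputError("library size must be positive")
    return (np.asarray(counts, float) * 1e6 / library_size) / rna_tpm


def normalize_profiles(
    profiles: ProfileSet,
    rna_tpm: Mapping[str, pd.Series],
    min_tpm: float = 1.0,
) -> tuple[ProfileSet, list[str]]:
    """Normalize every profile for library size and mRNA abundance (TPM).

    ``rna_tpm`` maps condition -> per-transcript TPM. Transcripts below
    ``min_tpm`` in any condition are excluded and reported.
    """
    excluded: set[str] = set()
    for cond in profiles.conditions():
        tpm_c = rna_tpm[cond]
        for tid in profiles.transcripts():
            if tid not in tpm_c.index or tpm_c[tid] < min_tpm:
                excluded.add(tid)
    out = ProfileSet()
    for cond in profiles.conditions():
        for rep in profiles.replicates(cond):
            lib = profiles.library_size(cond, rep)
            for tid in profiles.transcripts():
                if tid in excluded:
                    continue
                out.add(
                    tid, cond, rep,
                    normalized_occupancy(profiles.get(tid, cond, rep), lib, float(rna_tpm[cond][tid])),
                )
    return out, sorted(excluded)


def occupancy_delta(
    kd: ProfileSet, ctrl: ProfileSet | None = None, kd_label: str = "kd", ctrl_label: str = "ctrl"
) -> dict[str, np.ndarray]:
    """Replicate-averaged per-codon occupancy change (knockdown - control).

    Accepts either one ProfileSet holding both conditions, or two sets.
    Replicate labels must match between conditions.
    """
    if ctrl is None:
        ctrl = kd
    reps_kd = kd.replicates(kd_label)
    reps_ctrl = ctrl.replicates(ctrl_label)
    if reps_kd != reps_ctrl:
        raise InputError(f"replicate mismatch: {reps_kd} vs {reps_ctrl}")
    deltas: dict[str, np.ndarray] = {}
    common = sorted(set(kd.transcripts()) & set(ctrl.transcripts()))
    for tid in common:
        per_rep = [
            kd.get(tid, kd_label, rep) - ctrl.get(tid, ctrl_label, rep) for rep in reps_kd
        ]
        deltas[tid] = np.mean(per_rep, axis=0)
    return deltas


def bin_codon_values(values: np.ndarray, n_bins: int = 40) -> np.ndarray:
    """Per-bin mean of a per-codon vector; empty bins are NaN."""
    values = np.asarray(values, float)
    bins = positional_bins(len(values), n_bins)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            out[b] = values[sel].mean()
    return out


def metagene_binned(
    deltas: Mapping[str, np.ndarray], group: Iterable[str], n_bins: int = 40
) -> np.ndarray:
    """Group median of per-transcript binned occupancy deltas (40 windows)."""
    group = [g for g in group if g in deltas]
    if not group:
        raise InputError("empty transcript group")
    mat = np.vstack([bin_codon_values(deltas[g], n_bins) for g in group])
    return np.nanmedian(mat, axis=0)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Size factors from the median ratio to the geometric reference sample."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)  # geometric mean over samples; NaN if any zero
    usable = log_ref.notna()
    if not usable.any():
        raise InputError("no transcript observed in every sample; cannot form reference")
    log_ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(log_ratios.median(axis=0))


def log2fc_counts(
    counts: pd.DataFrame,
    kd_cols: Sequence[str],
    ctrl_cols: Sequence[str],
    pseudocount: float = 0.5,
    min_count: int = 10,
    min_samples: int = 3,
) -> pd.Series:
    """Per-transcript log2 fold change, knockdown over control.

    Transcripts must reach ``min_count`` reads in at least ``min_samples``
    samples; columns are scaled by median-of-ratios size factors before the
    pseudocounted ratio of condition means.
    """
    cols = list(kd_cols) + list(ctrl_cols)
    sub = counts[cols]
    keep = (sub >= min_count).sum(axis=1) >= min_samples
    sub = sub.loc[keep]
    if sub.empty:
        return pd.Series(dtype=float, name="log2fc")
    sf = median_of_ratios_size_factors(sub)
    norm = sub / sf
    kd_mean = norm[list(kd_cols)].mean(axis=1)
    ctrl_mean = norm[list(ctrl_cols)].mean(axis=1)
    out = np.log2((kd_mean + pseudocount) / (ctrl_mean + pseudocount))
    out.name = "log2fc"
    return out


def translational_efficiency(
    log2fc_rpf: pd.Series,
    log2fc_rna: pd.Series,
    increase_threshold: float = 0.2,
    none_threshold: float = 0.1,
) -> pd.DataFrame:
    """TE change and class per transcript: log2FC RPF - log2FC RNA.

    Classes: increased (te > 0.2), decreased (te < -0.2), none
    (|te| < 0.1), otherwise unclassified (the 0.1-0.2 gap).
    """
    common = log2fc_rpf.index.intersection(log2fc_rna.index)
    te = log2fc_rpf[common] - log2fc_rna[common]

    def classify(v: float) -> str:
        if math.isnan(v):
            return "unclassified"
        if v > increase_threshold:
            return "increased"
        if v < -increase_threshold:
            return "decreased"
        if -none_threshold < v < none_threshold:
            return "none"
        return "unclassified"

    return pd.DataFrame(
        {
            "log2fc_rpf": log2fc_rpf[common],
            "log2fc_rna": log2fc_rna[common],
            "log2fc_te": te,
            "te_class": te.map(classify),
        }
    )


def stability_groups(
    te_class: pd.Series,
    log2fc_half_life: pd.Series,
    split: float | str = "median",
) -> pd.Series:
    """Six-way mRNA fate label: TE class x low/high stability change.

    ``split`` is the log2 half-life change separating the strata; the
    default uses the median over classified transcripts.
    """
    common = te_class.index.intersection(log2fc_half_life.dropna().index)
    tc = te_class[common]
    hl = log2fc_half_life[common]
    valid = tc.isin(["increased", "none", "decreased"])
    cut = float(hl[valid].median()) if split == "median" else float(split)
    labels = pd.Series(pd.NA, index=common, dtype="object", name="stability_group")
    strata = np.where(hl > cut, "high-stability", "low-stability")
    labels[valid] = tc[valid] + "-TE/" + pd.Series(strata, index=common)[valid]
    return labels
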
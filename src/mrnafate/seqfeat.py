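"""CDS composition features, codon/amino-acid usage, and codon-stability association.

Frequencies are computed over sense codons: stop codons encode no residue
and are excluded everywhere, and codons containing N are dropped from both
numerator and denominator. GC3 is the fraction of sense codons ending in
G or C — the wobble-position signature separating "optimal"-leaning from
"non-optimal"-leaning codon usage.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import (
    AMINO_ACIDS,
    DISORDER_AAS,
    FAMILIES,
    GENETIC_CODE,
    SENSE_CODONS,
    third_nt,
    translate_cds,
)
from .core_io import Transcript


def _sense_codon_counts(t: Transcript) -> Counter:
    return Counter(c for c in t.codons() if c in GENETIC_CODE)


def codon_frequencies(t: Transcript) -> pd.Series:
    """Fraction of each of the 61 sense codons among the CDS's sense codons."""
    counts = _sense_codon_counts(t)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{t.id}: no sense codons")
    return pd.Series({c: counts.get(c, 0) / total for c in SENSE_CODONS}, name=t.id)


def gc3(t: Transcript) -> float:
    """Fraction of sense codons with G or C at the third position."""
    counts = _sense_codon_counts(t)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{t.id}: no sense codons")
    return sum(n for c, n in counts.items() if c[2] in "GC") / total


def synonymous_codon_usage(t: Transcript) -> pd.Series:
    """Per-codon fraction within its synonymous family; NaN for absent families."""
    counts = _sense_codon_counts(t)
    out: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        fam_total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = counts.get(c, 0) / fam_total if fam_total else np.nan
    return pd.Series(out, name=t.id)[list(SENSE_CODONS)]


def amino_acid_frequencies(t: Transcript) -> pd.Series:
    """Per-amino-acid fraction of sense codons; zeros stored as NaN.

    Zero frequencies are recorded as missing so that group averages skip
    mRNAs that never use the residue.
    """
    counts = _sense_codon_counts(t)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{t.id}: no sense codons")
    aa_counts = Counter()
    for c, n in counts.items():
        aa_counts[GENETIC_CODE[c]] += n
    out = {aa: (aa_counts[aa] / total if aa_counts[aa] else np.nan) for aa in AMINO_ACIDS}
    return pd.Series(out, name=t.id)


def disorder_fraction(t: Transcript) -> float:
    """Fraction of encoded residues that are disorder-promoting (P, Q, E, S, K)."""
    pep = translate_cds(t.cds_seq)
    if not pep:
        raise ValueError(f"{t.id}: no translatable codons")
    return sum(aa in DISORDER_AAS for aa in pep) / len(pep)


def positional_bins(length: int, n_bins: int) -> np.ndarray:
    """Bin index floor(n_bins * pos / length) for each position; partitions all positions."""
    pos = np.arange(length)
    return np.minimum((n_bins * pos) // length, n_bins - 1).astype(int)


def disorder_positional_profile(
    group: Sequence[Transcript], n_bins: int = 40
) -> np.ndarray:
    """Mean per-bin disorder fraction across a group of transcripts.

    Each residue goes to bin floor(n_bins * pos / len); bins a short CDS
    leaves empty are excluded from that transcript's profile (NaN), and
    the group mean skips them.
    """
    if not group:
        raise ValueError("empty transcript group")
    profiles = np.full((len(group), n_bins), np.nan)
    for row, t in enumerate(group):
        pep = translate_cds(t.cds_seq)
        if not pep:
            continue
        bins = positional_bins(len(pep), n_bins)
        dis = np.fromiter((aa in DISORDER_AAS for aa in pep), float, len(pep))
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                profiles[row, b] = dis[sel].mean()
    return np.nanmean(profiles, axis=0)


def build_feature_table(
    transcripts: Sequence[Transcript],
    targets: pd.DataFrame | None = None,
    include_codons: bool = True,
    include_amino_acids: bool = True,
) -> pd.DataFrame:
    """Per-transcript feature table for association and influence modelling.

    Scalar composition features (CDS length in codons, GC and AG and GC3
    content, UTR lengths, disorder fraction) plus, optionally, the
    61-codon and 20-amino-acid frequency vectors. ``targets`` columns
    (e.g. log2fc_half_life, te_class) are joined on transcript id.
    """
    rows = []
    for t in transcripts:
        seq = t.cds_seq
        n = len(seq)
        row = {
            "transcript_id": t.id,
            "cds_len": t.n_codons,
            "gc_cds": (seq.count("G") + seq.count("C")) / n,
            "ag_cds": (seq.count("A") + seq.count("G")) / n,
            "gc3": gc3(t),
            "utr5_len": t.utr5_len,
            "utr3_len": t.utr3_len,
            "disorder_fraction": disorder_fraction(t),
        }
        if include_codons:
            row.update({f"codon_{c}": v for c, v in codon_frequencies(t).items()})
        if include_amino_acids:
            aa = amino_acid_frequencies(t).fillna(0.0)
            row.update({f"aa_{a}": v for a, v in aa.items()})
        rows.append(row)
    feats = pd.DataFrame(rows).set_index("transcript_id")
    if targets is not None:
        feats = feats.join(targets, how="left")
    return feats


def codon_stability_correlation(
    features: pd.DataFrame, target: str = "log2fc_half_life", min_n: int = 10
) -> pd.DataFrame:
    """Spearman rho of each sense codon's frequency with a stability change.

    One row per sense codon with rho, n, the third nucleotide (A/U/G/C)
    and the encoded amino acid. Codons with constant frequency across
    transcripts get a missing rho.
    """
    if target not in features.columns:
        raise ValueError(f"missing target column {target!r}")
    sub = features.dropna(subset=[target])
    if len(sub) < min_n:
        raise ValueError(f"need >= {min_n} transcripts with non-missing {target}")
    y = sub[target].to_numpy()
    rows = []
    for codon in SENSE_CODONS:
        col = f"codon_{codon}"
        if col not in sub.columns:
            raise ValueError(f"feature table lacks codon columns ({col})")
        x = sub[col].to_numpy()
        if np.ptp(x) == 0:
            rho = np.nan
        else:
            rho = stats.spearmanr(x, y).statistic
        rows.append(
            {
                "codon": codon,
                "rho": rho,
                "n": len(sub),
                "third_nt": third_nt(codon),
                "amino_acid": GENETIC_CODE[codon],
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def prefilter_correlated(
    features: pd.DataFrame,
    r_max: float = 0.7,
    priority: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy de-correlation: keep one of each highly correlated feature pair.

    Walking the columns in ``priority`` order (table order by default), a
    feature is kept iff its absolute Pearson correlation with every
    already-kept feature is <= r_max. Returns the reduced table and the
    dropped (dropped, kept, r) pairs.
    """
    cols = list(priority) if priority is not None else list(features.columns)
    if len(cols) < 2 or len(features) < 3:
        raise ValueError("need >= 2 features and >= 3 rows")
    corr = features[cols].corr(method="pearson").abs()
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for col in cols:
        offender = next((k for k in kept if corr.loc[col, k] > r_max), None)
        if offender is None:
            kept.append(col)
        else:
            dropped.append((col, offender, float(corr.loc[col, offender])))
    return features[kept], dropped
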
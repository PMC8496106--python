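"""Shared transcript model, table I/O, and configuration.

All tabular data moves through tab-separated UTF-8 text with '.' decimals.
Transcript coordinates are 0-based, half-open, in nucleotides within the CDS
unless an operation documents codon units.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mrnafate")

START_CODONS = frozenset({"ATG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class InputError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class Transcript:
    """One representative transcript per gene.

    ``cds_seq`` is the coding sequence in the DNA alphabet (A/C/G/T/N),
    uppercased, with a length divisible by 3. UTR lengths are kept in
    nucleotides so positional operations can convert between transcript
    and CDS coordinates.
    """

    id: str
    cds_seq: str
    utr5_len: int = 0
    utr3_len: int = 0

    def __post_init__(self) -> None:
        if len(self.cds_seq) < 6 or len(self.cds_seq) % 3 != 0:
            raise ValueError(
                f"{self.id}: CDS length {len(self.cds_seq)} is not >= 6 and divisible by 3"
            )
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.id}: negative UTR length")

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    def codons(self) -> list[str]:
        s = self.cds_seq
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def is_complete(self) -> bool:
        """Starts with a start codon and ends with a stop codon."""
        return self.cds_seq[:3] in START_CODONS and self.cds_seq[-3:] in STOP_CODONS


@dataclass
class CountTable:
    """Counts or abundances: transcripts x samples, plus per-sample metadata.

    ``values`` is indexed by transcript id; ``samples`` is indexed by the
    column labels of ``values`` and carries whatever of condition /
    replicate / timepoint / fraction the experiment defines.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise InputError("negative values in count table")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise InputError(f"samples missing metadata: {missing}")

    def columns_where(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return [c for c in self.values.columns if mask.get(c, False)]


# Tunables for every stage; defaults follow the study design this package
# models (seven shutoff timepoints, three replicates, ROUT Q = 5% with a
# 20% outlier cap, 27-31 nt footprints with E/P/A offsets 9/12/15 nt,
# 10x pause rule with (15, 5) codon exclusion zones, 40 metagene windows,
# gbm-style boosting settings).
@dataclass
class Config:
    seed: int = 0
    # decay model
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    n_replicates: int = 3
    outlier_q: float = 0.05
    max_outlier_frac: float = 0.2
    # ribosome profiling
    read_length_range: tuple[int, int] = (25, 35)
    retained_read_lengths: tuple[int, ...] = (27, 28, 29, 30, 31)
    frame_threshold: float = 0.5
    psite_offsets: Mapping[str, int] = field(
        default_factory=lambda: {"E": 9, "P": 12, "A": 15}
    )
    min_tpm: float = 1.0
    te_increase_threshold: float = 0.2
    te_none_threshold: float = 0.1
    pseudocount: float = 0.5
    # pause calling
    pause_fold: float = 10.0
    exclusion_zone: tuple[int, int] = (15, 5)
    pause_mean_nonzero_only: bool = False
    # metagene / positional profiles
    n_bins: int = 40
    # feature influence
    n_trees: int = 200
    interaction_depth: int = 6
    shrinkage: float = 0.005
    cv_folds: int = 10
    r_max: float = 0.7
    # localization
    kmeans_n_init: int = 25
    kmeans_k_max: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read a flat ``key = value`` text config; '#' starts a comment."""
        overrides: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise InputError(f"{path}:{lineno}: unknown key {key!r}")
            overrides[key] = _parse_value(raw, getattr(cls(), key))
        return cls(**overrides)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", dataclasses.asdict(self))


def _parse_value(raw: str, default: object) -> object:
    if isinstance(default, bool):
        return raw.lower() in {"1", "true", "yes"}
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    if isinstance(default, tuple):
        parts = [p for p in raw.replace(",", " ").split() if p]
        elem = type(default[0]) if default else float
        return tuple(elem(p) for p in parts)
    return raw


def read_fasta_cds(path: str | Path) -> list[Transcript]:
    """Read CDS records from FASTA.

    Sequences are uppercased and U is mapped to T. Records whose length is
    not >= 6 and divisible by 3 are skipped with a warning (and counted in
    the log), never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise InputError(f"duplicate transcript id in FASTA: {rec.id}")
        seen.add(rec.id)
        if len(seq) < 6 or len(seq) % 3 != 0:
            logger.warning(
                "skipping %s: CDS length %d not >= 6 and divisible by 3", rec.id, len(seq)
            )
            n_skipped += 1
            continue
        transcripts.append(Transcript(id=rec.id, cds_seq=seq))
    if n_skipped:
        logger.warning("skipped %d records failing the CDS-length invariant", n_skipped)
    if not transcripts and n_skipped == 0:
        logger.warning("empty FASTA: %s", path)
    read_fasta_cds.last_skip_count = n_skipped  # type: ignore[attr-defined]
    return transcripts


def write_fasta_cds(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.cds_seq), 60):
                fh.write(t.cds_seq[i : i + 60] + "\n")


def read_count_table(
    path: str | Path,
    schema: pd.DataFrame | Mapping[str, Mapping[str, object]] | None = None,
) -> CountTable:
    """Read a TSV count table (first column: transcript id).

    ``schema`` maps each sample column to its metadata (condition,
    replicate, timepoint, ...). When omitted, metadata is parsed from
    column labels of the form ``condition_replicate_timepoint``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate transcript ids: {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise InputError(f"non-numeric values in {path}")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise InputError(
            f"negative value at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if schema is None:
        samples = parse_sample_labels(df.columns)
    elif isinstance(schema, pd.DataFrame):
        samples = schema
    else:
        samples = pd.DataFrame.from_dict(dict(schema), orient="index")
    missing = [c for c in df.columns if c not in samples.index]
    if missing:
        raise InputError(f"no metadata for columns: {missing}")
    return CountTable(values=df, samples=samples.loc[list(df.columns)])


def parse_sample_labels(labels: Iterable[str]) -> pd.DataFrame:
    """Parse ``condition_replicate_timepoint`` sample labels.

    The third field is optional; ``t<float>`` timepoints keep their hours.
    """
    rows = {}
    for label in labels:
        parts = label.split("_")
        if len(parts) < 2:
            raise InputError(
                f"cannot parse sample label {label!r}; expected condition_rep[_t<h>]"
            )
        meta: dict[str, object] = {"condition": parts[0], "replicate": parts[1]}
        if len(parts) >= 3:
            tp = parts[2]
            meta["timepoint"] = float(tp[1:]) if tp.startswith("t") else tp
        rows[label] = meta
    return pd.DataFrame.from_dict(rows, orient="index")


def write_table(table: pd.DataFrame, path: str | Path, precision: int = 6) -> None:
    """Write a TSV with header; floats rendered to ``precision`` significant digits."""
    table.to_csv(path, sep="\t", float_format=f"%.{precision}g", index=not _is_rangeindex(table))


def _is_rangeindex(df: pd.DataFrame) -> bool:
    return isinstance(df.index, pd.RangeIndex)
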
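"""Synthetic data with the statistical structure the downstream analyses assume.

The generator emulates a transcriptional-shutoff decay experiment (seven
timepoints, three replicates, values anchored at 100 at 0 h), a codon-biased
transcriptome in which the stability response to deadenylase-complex
depletion depends on GC3, two-condition ribosome-profiling count tables
with planted translational-efficiency shifts and pause peaks, and
ER/cytosol fractionation counts with spike-in rows.

All randomness flows from one seed; each generator op draws from its own
``numpy.random.default_rng([seed, op_tag])`` stream so outputs do not
depend on the order ops are called in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import AMINO_ACIDS, AU_ENDING, FAMILIES, GC_ENDING
from .core_io import CountTable, Transcript
from .ribo import ProfileSet
from .seqfeat import gc3 as _gc3

LN2 = math.log(2.0)

_OP_TRANSCRIPTOME, _OP_DECAY, _OP_RIBO, _OP_FRACTIONS = 1, 2, 3, 4

PAUSE_CLASSES = ("sustained", "resolved", "induced")
TE_CLASSES = ("increased", "none", "decreased")


@dataclass
class SimulationSpec:
    """Study-design parameters for the synthetic experiment.

    Defaults follow the modelled study: timepoints 0/0.5/1/2/4/8/16 h with
    three replicates, a median control half-life of 6.7 h, a mean log2
    half-life change of 2.1 after knockdown, and footprint/RNA counts with
    negative-binomial (Gamma-Poisson) noise.
    """

    n_transcripts: int = 500
    # CDS length distribution, log-normal in codons
    cds_len_log_mean: float = math.log(400.0)
    cds_len_log_sigma: float = 0.5
    cds_len_min: int = 60
    gc3_bias_range: tuple[float, float] = (0.0, 1.0)
    # half-life model
    halflife_median_ctrl: float = 6.7  # hours
    halflife_log2_sigma: float = 1.0
    halflife_effect_mean: float = 2.1  # mean Δlog2 half-life, knockdown vs control
    halflife_effect_beta: float = 2.0  # slope of Δlog2 half-life on centred GC3
    halflife_effect_sd: float = 0.25
    # decay time course
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    n_replicates: int = 3
    noise_cv: float = 0.1
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    # ribosome profiling
    rpf_rate_per_codon: float = 2.0
    rna_mean_count: float = 2000.0
    nb_size: float = 1000.0  # Gamma-Poisson size; dispersion = 1/size (technical noise floor)
    abundance_log2_sigma: float = 1.0
    te_shift_log2: float = 1.0
    te_class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    pause_rate: float = 0.5
    pause_fold: float = 50.0
    # fractionation
    er_props: tuple[float, float] = (0.1, 0.9)
    er_prop_jitter: float = 0.02
    n_spikeins: int = 20
    fraction_mean_count: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.outlier_rate, *self.gc3_bias_range, *self.er_props):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/proportion {p} outside [0, 1]")
        if abs(sum(self.te_class_probs) - 1.0) > 1e-9:
            raise ValueError("te_class_probs must sum to 1")
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if math.exp(self.cds_len_log_mean) <= 2 or self.cds_len_min <= 2:
            raise ValueError("degenerate CDS length distribution (<= 2 codons)")

    def rng(self, op_tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, op_tag])


@dataclass
class GroundTruth:
    """Planted quantities, mutually consistent with the emitted tables."""

    transcripts: pd.DataFrame  # indexed by transcript id
    pauses: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "codon_index", "pause_class", "fold"]
        )
    )
    outliers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "condition", "replicate", "timepoint"]
        )
    )

    def __post_init__(self) -> None:
        tr = self.transcripts
        for cond in ("ctrl", "kd"):
            prod = tr[f"halflife_{cond}"] * tr[f"k_{cond}"]
            if not np.allclose(prod, LN2):
                raise ValueError("inconsistent ground truth: t1/2 * k != ln 2")


def _draw_codon(aa: str, theta: float, rng: np.random.Generator) -> str:
    """Synonymous codon for ``aa``: G/C-ending with probability theta."""
    fam = FAMILIES[aa]
    gc = [c for c in fam if c in GC_ENDING]
    au = [c for c in fam if c in AU_ENDING]
    pool = gc if (rng.random() < theta or not au) else (au or gc)
    return pool[rng.integers(len(pool))]


def simulate_transcriptome(spec: SimulationSpec) -> tuple[list[Transcript], GroundTruth]:
    """Draw a codon-biased transcriptome and its planted per-transcript truth.

    Amino-acid sequences are uniform over the 20 residues; each synonymous
    codon is G/C-ending with per-transcript probability theta drawn uniform
    over ``gc3_bias_range``. The stability change after knockdown is
    Δlog2 t1/2 = effect_mean + beta * (GC3 - mean GC3) + Gaussian noise.
    """
    rng = spec.rng(_OP_TRANSCRIPTOME)
    n = spec.n_transcripts
    lens = np.maximum(
        rng.lognormal(spec.cds_len_log_mean, spec.cds_len_log_sigma, n).astype(int),
        spec.cds_len_min,
    )
    thetas = rng.uniform(*spec.gc3_bias_range, n)

    transcripts: list[Transcript] = []
    gc3_vals = np.empty(n)
    for i in range(n):
        theta = thetas[i]
        aas = rng.choice(len(AMINO_ACIDS), size=lens[i] - 1)
        codons = ["ATG"] + [_draw_codon(AMINO_ACIDS[a], theta, rng) for a in aas]
        stop = "TAG" if rng.random() < theta else ("TAA", "TGA")[rng.integers(2)]
        t = Transcript(id=f"tx{i:05d}", cds_seq="".join(codons) + stop)
        transcripts.append(t)
        gc3_vals[i] = _gc3(t)

    hl_ctrl = spec.halflife_median_ctrl * np.exp2(
        rng.normal(0.0, spec.halflife_log2_sigma, n)
    )
    dlog2 = (
        spec.halflife_effect_mean
        + spec.halflife_effect_beta * (gc3_vals - gc3_vals.mean())
        + rng.normal(0.0, spec.halflife_effect_sd, n)
    )
    hl_kd = hl_ctrl * np.exp2(dlog2)

    te_class = rng.choice(TE_CLASSES, size=n, p=spec.te_class_probs)
    abundance = np.exp2(rng.normal(0.0, spec.abundance_log2_sigma, n))
    er_mode = rng.integers(2, size=n)
    er_prop = np.clip(
        np.asarray(spec.er_props)[er_mode] + rng.normal(0.0, spec.er_prop_jitter, n),
        0.0,
        1.0,
    )

    truth_tr = pd.DataFrame(
        {
            "n_codons": [t.n_codons for t in transcripts],
            "theta": thetas,
            "gc3": gc3_vals,
            "halflife_ctrl": hl_ctrl,
            "halflife_kd": hl_kd,
            "k_ctrl": LN2 / hl_ctrl,
            "k_kd": LN2 / hl_kd,
            "log2fc_halflife": dlog2,
            "te_class": te_class,
            "abundance": abundance,
            "er_proportion": er_prop,
            "er_class": np.where(er_mode == 1, "er", "cyto"),
        },
        index=pd.Index([t.id for t in transcripts], name="transcript_id"),
    )

    # plant at most one pause per transcript, outside the (15, 5) exclusion zones
    pause_rows = []
    for t in transcripts:
        if rng.random() >= spec.pause_rate:
            continue
        lo, hi = 15, t.n_codons - 6
        if hi <= lo:
            continue
        pause_rows.append(
            {
                "transcript_id": t.id,
                "codon_index": int(rng.integers(lo, hi + 1)),
                "pause_class": PAUSE_CLASSES[rng.integers(3)],
                "fold": spec.pause_fold,
            }
        )
    pauses = pd.DataFrame(
        pause_rows, columns=["transcript_id", "codon_index", "pause_class", "fold"]
    )
    return transcripts, GroundTruth(transcripts=truth_tr, pauses=pauses)


def simulate_decay_course(spec: SimulationSpec, truth: GroundTruth) -> CountTable:
    """Exponential-decay time courses y(t) = 100 * exp(-k t) with noise.

    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (unit mean); with probability ``outlier_rate`` a non-zero
    timepoint is multiplied or divided (fair coin) by ``outlier_scale``.
    0 h values are exactly 100, since downstream normalization anchors
    there. Outlier locations are recorded in the ground truth.
    """
    rng = spec.rng(_OP_DECAY)
    tr = truth.transcripts
    ids = tr.index.to_numpy()
    tps = np.asarray(spec.timepoints)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))

    cols: dict[str, np.ndarray] = {}
    sample_meta: dict[str, dict[str, object]] = {}
    outlier_rows = []
    for cond in ("ctrl", "kd"):
        k = tr[f"k_{cond}"].to_numpy()
        for rep in range(1, spec.n_replicates + 1):
            for t in tps:
                label = f"{cond}_r{rep}_t{t:g}"
                sample_meta[label] = {
                    "condition": cond,
                    "replicate": f"r{rep}",
                    "timepoint": float(t),
                }
                if t == 0.0:
                    vals = np.full(len(ids), 100.0)
                else:
                    eps = np.exp(rng.normal(-0.5 * sigma**2, sigma, len(ids)))
                    vals = 100.0 * np.exp(-k * t) * eps
                    hit = rng.random(len(ids)) < spec.outlier_rate
                    if hit.any():
                        updown = rng.random(hit.sum()) < 0.5
                        factor = np.where(updown, spec.outlier_scale, 1.0 / spec.outlier_scale)
                        vals[hit] = vals[hit] * factor
                        for tid in ids[hit]:
                            outlier_rows.append(
                                {
                                    "transcript_id": tid,
                                    "condition": cond,
                                    "replicate": f"r{rep}",
                                    "timepoint": float(t),
                                }
                            )
                cols[label] = vals

    truth.outliers = pd.DataFrame(
        outlier_rows, columns=["transcript_id", "condition", "replicate", "timepoint"]
    )
    values = pd.DataFrame(cols, index=pd.Index(ids, name="transcript_id"))
    return CountTable(values=values, samples=pd.DataFrame.from_dict(sample_meta, orient="index"))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Gamma-Poisson counts with the given mean and NB size parameter."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_ribo_counts(
    spec: SimulationSpec, truth: GroundTruth
) -> tuple[ProfileSet, CountTable]:
    """Two-condition P-site codon counts plus matched RNA counts.

    Per-codon footprint counts are Gamma-Poisson around a per-transcript
    rate; knockdown rates carry the planted log2 TE shift; planted pause
    codons are elevated ``fold``-fold in the conditions their class
    dictates (sustained: both; resolved: control only; induced: knockdown
    only). RNA counts track the planted abundance and do not change
    between conditions, so the planted TE shift is carried by the
    footprints alone.
    """
    rng = spec.rng(_OP_RIBO)
    tr = truth.transcripts
    rel_abund = tr["abundance"] / tr["abundance"].mean()

    pause_by_tid: dict[str, list[tuple[int, str, float]]] = {}
    for row in truth.pauses.itertuples(index=False):
        n_codons = int(tr.loc[row.transcript_id, "n_codons"])
        if not 15 <= row.codon_index <= n_codons - 6:
            raise ValueError(
                f"planted pause at codon {row.codon_index} of {row.transcript_id} "
                "is inside the (15, 5) exclusion zones"
            )
        pause_by_tid.setdefault(row.transcript_id, []).append(
            (int(row.codon_index), str(row.pause_class), float(row.fold))
        )

    te_dir = {"increased": 1.0, "none": 0.0, "decreased": -1.0}
    profiles = ProfileSet()
    rna_cols: dict[str, np.ndarray] = {}
    rna_meta: dict[str, dict[str, object]] = {}

    for cond in ("ctrl", "kd"):
        for rep in range(1, spec.n_replicates + 1):
            label = f"{cond}_r{rep}"
            rna_meta[label] = {"condition": cond, "replicate": f"r{rep}"}
            rna_cols[label] = _nb_draw(
                rng, rel_abund.to_numpy() * spec.rna_mean_count, spec.nb_size
            )
            for tid, n_codons, ra, te_class in zip(
                tr.index, tr["n_codons"], rel_abund, tr["te_class"]
            ):
                rate = spec.rpf_rate_per_codon * ra
                if cond == "kd":
                    rate *= 2.0 ** (spec.te_shift_log2 * te_dir[te_class])
                mu = np.full(int(n_codons), rate)
                for codon_idx, pclass, fold in pause_by_tid.get(tid, []):
                    active = (
                        pclass == "sustained"
                        or (pclass == "resolved" and cond == "ctrl")
                        or (pclass == "induced" and cond == "kd")
                    )
                    if active:
                        mu[codon_idx] *= fold
                profiles.add(tid, cond, f"r{rep}", _nb_draw(rng, mu, spec.nb_size))

    rna = CountTable(
        values=pd.DataFrame(rna_cols, index=tr.index.copy()),
        samples=pd.DataFrame.from_dict(rna_meta, orient="index"),
    )
    return profiles, rna


def simulate_fraction_counts(spec: SimulationSpec, truth: GroundTruth) -> CountTable:
    """ER/cytosol fraction counts with ERCC-style spike-in rows.

    Each transcript's molecules split between the ER and cytosolic
    fractions according to its planted proportion; spike-ins have equal
    true amounts in both fractions and scale only with each fraction's
    sequencing depth.
    """
    rng = spec.rng(_OP_FRACTIONS)
    tr = truth.transcripts
    prop = tr["er_proportion"].to_numpy()
    if ((prop < 0) | (prop > 1)).any():
        raise ValueError("ER proportions outside [0, 1]")
    rel_abund = (tr["abundance"] / tr["abundance"].mean()).to_numpy()
    spike_amount = np.exp2(rng.normal(3.0, 1.0, spec.n_spikeins))

    cols: dict[str, np.ndarray] = {}
    meta: dict[str, dict[str, object]] = {}
    for cond in ("ctrl", "kd"):
        for fraction, frac_prop in (("cyto", 1.0 - prop), ("er", prop)):
            depth = np.exp2(rng.normal(0.0, 0.25))
            label = f"{cond}_{fraction}"
            meta[label] = {"condition": cond, "fraction": fraction, "replicate": "r1"}
            tx_mu = rel_abund * frac_prop * spec.fraction_mean_count * depth
            spike_mu = spike_amount * depth
            cols[label] = np.concatenate(
                [_nb_draw(rng, tx_mu, spec.nb_size), _nb_draw(rng, spike_mu, spec.nb_size)]
            )

    index = pd.Index(
        list(tr.index) + [f"ERCC-{i:05d}" for i in range(spec.n_spikeins)],
        name="transcript_id",
    )
    return CountTable(values=pd.DataFrame(cols, index=index), samples=pd.DataFrame.from_dict(meta, orient="index"))


def spikein_ids(table: CountTable) -> list[str]:
    """Rows flagged as spike-ins by the ERCC- prefix convention."""
    return [i for i in table.values.index if str(i).startswith("ERCC-")]
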
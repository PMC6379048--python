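"""Synthetic transcripts, expression data, conservation tracks and
auxiliary tables with known planted effects.

The generator mirrors the statistical structure the downstream model
assumes: tissue-specific log10 protein-to-mRNA ratios are an additive
function of realized codon log2 frequencies (per-doubling effects),
planted motif site counts, a tissue offset, binary covariates, and
per-cell Gaussian noise.  Expression data are emitted as exonic/intronic
negative-binomial counts with technical replicates and as iBAQ
intensities with multiplicative noise, per-tissue median shifts and
missingness below a detection floor, so the preprocessing stage has a
parameter-recovery test without any download.

All randomness flows from one seed through named substreams (one per
operation), so adding a stage never perturbs earlier stages.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ConservationTrack, CountTable, IbaqTable, SampleSheet, STOP_CODONS,
    TranscriptRecord, validate_transcript,
)
from .sequence_features import SENSE_CODONS, aa_log2_freq, codon_log2_freq, count_occurrences

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, name)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class PlantedMotif:
    motif: str                       # DNA alphabet
    region: Literal["utr5", "utr3"]
    effect: float                    # log10 PTR per site
    carrier_fraction: float
    conserved: bool = True


#: default planted motifs emulate the best-characterised 3'UTR elements
#: (polyadenylation signal, AU-rich element, Pumilio site) and one 5'UTR
#: element, with log10-scale per-site effects of realistic magnitude.
DEFAULT_PLANTED = (
    PlantedMotif("AATAAA", "utr3", 0.083, 0.60),
    PlantedMotif("TATTTAT", "utr3", -0.041, 0.27),
    PlantedMotif("TGTAAATA", "utr3", -0.046, 0.11),
    PlantedMotif("CTGTCCT", "utr5", -0.050, 0.10),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_tissues: int = 8
    n_replicates: int = 2
    utr5_length_log_mean: float = float(np.log(180.0))
    utr5_length_log_sd: float = 0.35
    cds_codons_mean: int = 400
    utr3_length_log_mean: float = float(np.log(800.0))
    utr3_length_log_sd: float = 0.5
    background_gc: float = 0.45
    planted_motifs: tuple[PlantedMotif, ...] = DEFAULT_PLANTED
    codon_effect_sd: float = 0.05        # sd of true per-codon log10 effects per doubling
    codon_usage_concentration: float = 100.0
    gene_noise_sd: float = 0.15          # per-cell log10 noise
    tissue_effect_sd: float = 0.10       # log10 tissue offsets
    ptr_intercept: float = 1.0
    nb_dispersion: float = 0.05          # NB: var = mu + disp*mu^2; 0 = exact expected counts
    intronic_fraction: float = 0.10      # pre-mRNA signal as fraction of mature signal
    ibaq_noise_sd: float = 0.20          # log10 multiplicative noise on iBAQ
    tissue_median_shift_sd: float = 0.30 # log10 per-tissue shifts removed by median alignment
    detection_floor: float = 1.0         # iBAQ intensities below this are missing
    mrna_log_mean: float = 1.5           # log10 reads/kb of mature mRNA
    mrna_log_sd: float = 0.5
    intron_length_log_mean: float = float(np.log(20000.0))
    intron_length_log_sd: float = 0.8
    cons_background: tuple[float, float] = (2.0, 8.0)  # Beta(a,b), mean 0.2
    cons_motif: tuple[float, float] = (8.0, 2.0)       # Beta(a,b), mean 0.8
    binary_covariates: tuple[tuple[str, float, float], ...] = (
        ("rbp_target", 0.30, -0.05),
        ("mirna_target", 0.25, -0.04),
    )
    n_decoding_datasets: int = 5
    decoding_noise_sd: float = 0.3
    half_life_aa_effect_sd: float = 0.05
    half_life_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        for m in self.planted_motifs:
            if not (0.0 < m.carrier_fraction < 1.0):
                raise ValueError(f"carrier fraction of {m.motif} must lie in (0,1)")
        for name in ("codon_effect_sd", "gene_noise_sd", "tissue_effect_sd",
                     "ibaq_noise_sd", "tissue_median_shift_sd", "decoding_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    codon_effects: pd.Series            # 61, log10 per log2-frequency doubling
    motif_effects: dict[str, float]     # planted-motif label -> per-site effect
    true_ptr: pd.DataFrame | None = None        # genes x tissues, log10
    true_mrna: pd.Series | None = None          # log10 reads/kb, per gene
    tissue_offsets: pd.Series | None = None
    motif_sites: dict[tuple[str, str], list[tuple[int, int, str]]] = field(default_factory=dict)
    motif_counts: pd.DataFrame | None = None    # genes x planted motifs, realized counts
    exon_len: pd.Series | None = None
    intron_len: pd.Series | None = None
    covariates: pd.DataFrame | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    aa_half_life_effects: pd.Series | None = None


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _NT[rng.choice(4, size=n, p=p)].tobytes().decode()


def _plant(
    rng: np.random.Generator, seq: str, motif: str, forbidden: list[tuple[int, int]],
    lo: int, hi: int,
) -> tuple[str, int]:
    """Substitute ``motif`` at a uniform position in [lo, hi); re-draw on
    overlap with ``forbidden`` intervals (max 100 attempts)."""
    k = len(motif)
    if hi - lo < k:
        raise ValueError(f"motif {motif} (len {k}) does not fit region of length {len(seq)}")
    for _ in range(100):
        start = int(rng.integers(lo, hi - k + 1))
        if all(start + k <= a or start >= b for a, b in forbidden):
            return seq[:start] + motif + seq[start + k:], start
    raise RuntimeError(f"could not place motif {motif} without overlap after 100 attempts")


def simulate_transcripts(config: SimulationConfig) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Generate transcripts and the true per-doubling codon effects.

    CDS codons are drawn from per-gene codon-usage distributions (Dirichlet
    around the uniform base) so that realized codon log2 frequencies vary
    across genes; true codon effects are then realized exactly because the
    true PTR is computed from the realized frequencies.  Planted motifs are
    substituted in place at uniform positions in their region, never
    overlapping the start/stop context windows or each other.
    """
    n = config.n_genes
    rng_len = stream(config.seed, "lengths")
    rng_seq = stream(config.seed, "sequences")
    rng_usage = stream(config.seed, "codon_usage")
    rng_eff = stream(config.seed, "codon_effects")
    rng_car = stream(config.seed, "motif_carriers")
    rng_pos = stream(config.seed, "motif_positions")

    utr5_len = np.maximum(8, np.rint(np.exp(
        rng_len.normal(config.utr5_length_log_mean, config.utr5_length_log_sd, n)))).astype(int)
    utr3_len = np.maximum(8, np.rint(np.exp(
        rng_len.normal(config.utr3_length_log_mean, config.utr3_length_log_sd, n)))).astype(int)
    n_codons = np.maximum(40, rng_len.poisson(config.cds_codons_mean, n))

    codon_effects = pd.Series(
        rng_eff.normal(0.0, config.codon_effect_sd, 61),
        index=[f"codon:{c}" for c in SENSE_CODONS],
    )
    base = np.full(61, 1.0 / 61)
    usage = rng_usage.dirichlet(base * config.codon_usage_concentration, size=n)

    carriers = {
        m.motif + "@" + m.region: rng_car.random(n) < m.carrier_fraction
        for m in config.planted_motifs
    }

    records: list[TranscriptRecord] = []
    motif_sites: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    codons_arr = np.array(SENSE_CODONS)
    stop_arr = np.array(STOP_CODONS)
    for g in range(n):
        tid = f"tx{g:05d}"
        utr5 = _random_seq(rng_seq, utr5_len[g], config.background_gc)
        utr3 = _random_seq(rng_seq, utr3_len[g], config.background_gc)
        internal = codons_arr[rng_seq.choice(61, size=n_codons[g] - 1, p=usage[g])]
        cds = "ATG" + "".join(internal) + stop_arr[rng_seq.integers(3)]
        planted: dict[str, list[tuple[int, int]]] = {"utr5": [], "utr3": []}
        for m in config.planted_motifs:
            if not carriers[m.motif + "@" + m.region][g]:
                continue
            seq = utr5 if m.region == "utr5" else utr3
            # keep clear of the start context (5'UTR tail) / stop context (3'UTR head)
            lo, hi = (0, len(seq) - 6) if m.region == "utr5" else (3, len(seq))
            seq, start = _plant(rng_pos, seq, m.motif, planted[m.region], lo, hi)
            planted[m.region].append((start, start + len(m.motif)))
            motif_sites.setdefault((tid, m.region), []).append((start, start + len(m.motif), m.motif))
            if m.region == "utr5":
                utr5 = seq
            else:
                utr3 = seq
        rec = TranscriptRecord(tid, f"g{g:05d}", utr5, cds, utr3)
        report = validate_transcript(rec)
        if not report.ok:  # pragma: no cover - generation guarantees validity
            raise AssertionError(f"generated invalid record: {report.failures}")
        records.append(rec)

    motif_counts = pd.DataFrame(
        {
            f"{m.motif}@{m.region}": [
                count_occurrences(getattr(r, m.region), m.motif) for r in records
            ]
            for m in config.planted_motifs
        },
        index=[r.transcript_id for r in records],
    )
    truth = GroundTruth(
        codon_effects=codon_effects,
        motif_effects={f"{m.motif}@{m.region}": m.effect for m in config.planted_motifs},
        motif_sites=motif_sites,
        motif_counts=motif_counts,
    )
    return records, truth


# ---------------------------------------------------------------------------
# true PTR
# ---------------------------------------------------------------------------

def simulate_true_ptr(
    truth: GroundTruth, transcripts: Sequence[TranscriptRecord], config: SimulationConfig
) -> pd.DataFrame:
    """True log10 PTR = intercept + codon-effect term + motif term +
    covariate term + tissue offset + per-cell Gaussian noise."""
    rng_t = stream(config.seed, "tissue_offsets")
    rng_e = stream(config.seed, "gene_noise")
    rng_c = stream(config.seed, "covariates")
    ids = [r.transcript_id for r in transcripts]
    tissues = [f"T{j:02d}" for j in range(config.n_tissues)]

    codon_x = pd.DataFrame(
        [codon_log2_freq(r.cds) for r in transcripts], index=ids)
    base = config.ptr_intercept + codon_x.to_numpy() @ truth.codon_effects.to_numpy()
    if truth.motif_counts is not None and len(truth.motif_effects):
        eff = np.array([truth.motif_effects[c] for c in truth.motif_counts.columns])
        base = base + truth.motif_counts.to_numpy() @ eff

    cov_cols = {}
    for name, fraction, effect in config.binary_covariates:
        ind = (rng_c.random(len(ids)) < fraction).astype(float)
        cov_cols[name] = ind
        base = base + effect * ind
    truth.covariates = pd.DataFrame(cov_cols, index=ids)
    truth.covariate_effects = {name: eff for name, _, eff in config.binary_covariates}

    offsets = rng_t.normal(0.0, config.tissue_effect_sd, config.n_tissues)
    noise = rng_e.normal(0.0, config.gene_noise_sd, (len(ids), config.n_tissues))
    ptr = base[:, None] + offsets[None, :] + noise
    truth.true_ptr = pd.DataFrame(ptr, index=ids, columns=tissues)
    truth.tissue_offsets = pd.Series(offsets, index=tissues)
    return truth.true_ptr


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return np.rint(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_expression(
    truth: GroundTruth, transcripts: Sequence[TranscriptRecord], config: SimulationConfig
) -> tuple[CountTable, CountTable, IbaqTable, SampleSheet]:
    """Exonic/intronic counts, iBAQ intensities and the sample sheet.

    Exonic counts are negative binomial around (mature + pre-mRNA) signal
    scaled by exonic length; intronic counts around pre-mRNA signal scaled
    by intronic length.  With ``nb_dispersion = 0`` expected counts are
    emitted directly (noiseless limit); true mRNA densities are defined
    from integer exonic read totals so that the zero-noise pipeline
    recovers them exactly.  iBAQ = 10^(true log10 mRNA + true log10 PTR +
    noise + tissue shift), missing below the detection floor.
    """
    if truth.true_ptr is None:
        raise ValueError("call simulate_true_ptr first")
    rng_m = stream(config.seed, "mrna")
    rng_cnt = stream(config.seed, "counts")
    rng_ib = stream(config.seed, "ibaq")
    ids = [r.transcript_id for r in transcripts]
    tissues = list(truth.true_ptr.columns)

    exon_len = pd.Series({r.transcript_id: len(r.utr5) + len(r.cds) + len(r.utr3)
                          for r in transcripts})
    intron_len = pd.Series(
        np.maximum(200, np.rint(np.exp(rng_m.normal(
            config.intron_length_log_mean, config.intron_length_log_sd, len(ids))))).astype(int),
        index=ids)
    exon_kb = exon_len.to_numpy() / 1000.0
    intron_kb = intron_len.to_numpy() / 1000.0

    # integer mature read totals -> exactly representable densities
    reads = np.maximum(1, np.rint(
        10.0 ** rng_m.normal(config.mrna_log_mean, config.mrna_log_sd, len(ids)) * exon_kb
    )).astype(np.int64)
    density = reads / exon_kb
    truth.true_mrna = pd.Series(np.log10(density), index=ids)
    truth.exon_len, truth.intron_len = exon_len, intron_len

    sheet_rows, exonic_cols, intronic_cols = [], {}, {}
    f = config.intronic_fraction
    for t in tissues:
        for r in range(1, config.n_replicates + 1):
            sample = f"{t}_r{r}"
            sheet_rows.append((sample, t, r))
            exonic_mean = reads * (1.0 + f)
            intronic_mean = f * density * intron_kb
            exonic_cols[sample] = _nb_draw(rng_cnt, exonic_mean, config.nb_dispersion)
            intronic_cols[sample] = _nb_draw(rng_cnt, intronic_mean, config.nb_dispersion)

    shifts = stream(config.seed, "tissue_shifts").normal(
        0.0, config.tissue_median_shift_sd, len(tissues))
    ibaq = {}
    for j, t in enumerate(tissues):
        log_int = (truth.true_mrna.to_numpy() + truth.true_ptr[t].to_numpy()
                   + rng_ib.normal(0.0, config.ibaq_noise_sd, len(ids)) + shifts[j])
        vals = 10.0 ** log_int
        vals[vals < config.detection_floor] = np.nan
        ibaq[t] = vals

    sheet = SampleSheet(pd.DataFrame(sheet_rows, columns=["sample_id", "tissue", "replicate_index"]))
    exonic = CountTable(pd.DataFrame(exonic_cols, index=ids), "exonic")
    intronic = CountTable(pd.DataFrame(intronic_cols, index=ids), "intronic")
    return exonic, intronic, IbaqTable(pd.DataFrame(ibaq, index=ids)), sheet


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def simulate_conservation(
    transcripts: Sequence[TranscriptRecord], truth: GroundTruth, config: SimulationConfig,
    regions: Sequence[str] = ("utr5", "utr3"),
) -> ConservationTrack:
    """Beta-distributed per-base scores, elevated inside conserved planted
    motif instances."""
    rng = stream(config.seed, "conservation")
    a0, b0 = config.cons_background
    a1, b1 = config.cons_motif
    conserved_motifs = {m.motif for m in config.planted_motifs if m.conserved}
    frames = []
    for rec in transcripts:
        for region in regions:
            L = len(getattr(rec, region))
            scores = rng.beta(a0, b0, L)
            for start, end, motif in truth.motif_sites.get((rec.transcript_id, region), []):
                if motif in conserved_motifs:
                    scores[start:end] = rng.beta(a1, b1, end - start)
            frames.append(pd.DataFrame({
                "transcript_id": rec.transcript_id,
                "region": region,
                "position": np.arange(L),
                "score": scores,
            }))
    return ConservationTrack(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def simulate_auxiliary(
    truth: GroundTruth, config: SimulationConfig,
    transcripts: Sequence[TranscriptRecord] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Codon decoding-time tables, protein half-lives, binary covariates.

    Decoding times per dataset are affine transforms of one latent
    per-codon vector plus noise (exercising z-score aggregation);
    half-lives are generated from planted amino-acid effects on the
    transcripts' realized amino-acid frequencies.
    """
    rng_d = stream(config.seed, "decoding")
    rng_h = stream(config.seed, "half_life")
    latent = rng_d.normal(0.0, 1.0, 61)
    tables = {}
    for i in range(config.n_decoding_datasets):
        a = rng_d.normal(0.0, 5.0)
        b = abs(rng_d.normal(1.0, 0.5)) + 0.1
        tables[f"ds{i}"] = a + b * (latent + rng_d.normal(0.0, config.decoding_noise_sd, 61))
    decoding = pd.DataFrame(tables, index=list(SENSE_CODONS)).T

    if transcripts:
        ids = [r.transcript_id for r in transcripts]
        aa_x = pd.DataFrame([aa_log2_freq(r.cds) for r in transcripts], index=ids)
        aa_eff = pd.Series(rng_h.normal(0.0, config.half_life_aa_effect_sd, 20), index=aa_x.columns)
        log_hl = 1.0 + aa_x.to_numpy() @ aa_eff.to_numpy() + rng_h.normal(
            0.0, config.half_life_noise_sd, len(ids))
        half_life = pd.DataFrame({"half_life_log10": log_hl}, index=ids)
        truth.aa_half_life_effects = aa_eff
    else:
        half_life = pd.DataFrame(columns=["half_life_log10"])

    covariates = truth.covariates if truth.covariates is not None else pd.DataFrame()
    return decoding, half_life, covariates


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    transcripts: list[TranscriptRecord]
    truth: GroundTruth
    exonic: CountTable
    intronic: CountTable
    ibaq: IbaqTable
    sample_sheet: SampleSheet


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    transcripts, truth = simulate_transcripts(config)
    simulate_true_ptr(truth, transcripts, config)
    exonic, intronic, ibaq, sheet = simulate_expression(truth, transcripts, config)
    return SimulatedDataset(config, transcripts, truth, exonic, intronic, ibaq, sheet)
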
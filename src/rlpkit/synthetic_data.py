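"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the data-generating structure the analyses assume:
compartment-specific editing over a cytoplasmic background, 3'-positional
bias of edits (mass 50-250 nt upstream of the poly(A) site, where a
poly(A)-tail-binding reporter deposits most of its edits), a
chemistry-consistent dinucleotide motif at edited sites (TA for the A>G
chemistry, AC for C>T), uninduced controls carrying only a flat per-site
error rate, cell-to-cell detection heterogeneity (core genes edited in
>90% of cells, rare genes in <10%, the rest following an
expression-matched multinomial null), temporal localization classes
(rising / peaked / flat), and phase-dependent intron retention.

Every generator draws from a named substream of one top-level seed, so
outputs are byte-identical under a fixed seed and adding a generator never
perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .editing_caller import CHEMISTRIES, genomic_edit_bases
from .quantification import GeneEditProfile
from .singlecell_stats import CellMatrices
from .transcript_io import BASES, SiteCount, TranscriptModel

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass
class SimulationTruth:
    """All tunable parameters of the generators, serializable to JSON.

    Defaults describe the study conditions the package is tested under:
    a 300-gene transcriptome, 100 cells, 7 timepoints, editing placed at
    chemistry-consistent dinucleotides 50-250 nt upstream of the poly(A)
    site, clean controls, and a 10x S-vs-G2M intron-retention contrast.
    """

    seed: int = 0
    # transcriptome
    n_genes: int = 300
    motif: str = "TA"
    chemistry: str = "A>G"
    motif_density: float = 0.05
    # bulk editing
    frac_compartment: float = 0.3
    frac_unexpressed: float = 0.05
    editing_rate: float = 0.1
    sites_per_gene: int = 5
    background_sites_per_gene: int = 3
    positional_window: tuple[int, int] = (50, 250)
    control_noise: float = 0.0
    mean_depth: float = 100.0
    # temporal classes
    frac_rising: float = 0.4
    frac_peaked: float = 0.4
    n_timepoints: int = 7
    temporal_noise_sd: float = 0.3
    temporal_amplitude: float = 1.0
    base_efficiency: float = 0.01
    timecourse_reads: int = 100_000
    # cell model
    n_cells: int = 100
    core_fraction: float = 0.05
    rare_fraction: float = 0.05
    core_cell_prob: float = 0.95
    rare_cell_prob: float = 0.05
    planted_edit_mean: float = 6.0
    null_edits_per_cell: float = 1500.0
    hetero_fraction: float = 0.0
    hetero_cell_fraction: float = 0.1
    hetero_multiplier: float = 5.0
    # intron model
    retention_by_phase: dict = field(
        default_factory=lambda: {"S": 1.0, "G2M": 0.1}
    )
    flank_coverage_mean: float = 50.0
    coverage_noise_sd: float = 0.2

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.array(list(BASES)), size=length)


def _set_motif_density(
    seq: np.ndarray, motif: str, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Break all existing occurrences of ``motif``, then replant at the
    requested density (fraction of positions starting a motif)."""
    seq = seq.copy()
    others = [b for b in BASES if b != motif[1]]
    for i in range(len(seq) - 1):
        if seq[i] == motif[0] and seq[i + 1] == motif[1]:
            seq[i + 1] = rng.choice(others)
    if density > 0:
        n_plant = int(round(density * len(seq)))
        if n_plant:
            starts = rng.choice(len(seq) - 1, size=min(n_plant, len(seq) - 1),
                                replace=False)
            for s in sorted(starts):
                seq[s], seq[s + 1] = motif[0], motif[1]
    return seq


def make_transcriptome(
    n_genes: int = 300,
    seed: int = 0,
    motif: str = "TA",
    motif_density: float = 0.05,
    pad: int = 50,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Random transcript models and genome, one gene per contig.

    Each gene has 1-5 exons, a random strand, and exonic sequence carrying
    the target dinucleotide at the requested density (in transcript
    orientation). Deterministic under ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng_for(seed, "transcriptome")
    models: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    for g in range(n_genes):
        gene_id = f"G{g:04d}"
        contig = f"chr_{gene_id}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(50, 201, size=max(n_exons - 1, 0))
        exons = []
        cursor = pad
        for i, el in enumerate(exon_lens):
            exons.append((cursor, cursor + int(el)))
            cursor += int(el)
            if i < n_exons - 1:
                cursor += int(intron_lens[i])
        model = TranscriptModel(
            gene_id=gene_id, transcript_id=f"{gene_id}.t1", contig=contig,
            strand=strand, exons=tuple(exons),
            biotype="protein_coding" if rng.random() < 0.9 else "lncRNA",
        )
        # transcript sequence (5'->3') with controlled motif density
        tseq = _set_motif_density(
            _random_seq(rng, model.length), motif, motif_density, rng
        )
        contig_seq = _random_seq(rng, cursor + pad)
        for tpos in range(model.length):
            gpos = model.genomic_position(tpos)
            base = tseq[tpos]
            contig_seq[gpos] = base if strand == "+" else COMPLEMENT[base]
        # keep intron/padding sequence free of accidental strand-motif hits
        models.append(model)
        genome[contig] = "".join(contig_seq)
    return models, genome


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _eligible_sites(
    model: TranscriptModel, genome: dict[str, str], truth: SimulationTruth
) -> list[int]:
    """Transcript positions of chemistry-consistent motif sites inside the
    positional window (distance to poly(A) in [lo, hi))."""
    lo, hi = truth.positional_window
    contig = genome[model.contig]
    edited = CHEMISTRIES[truth.chemistry][0]
    out = []
    for tpos in range(1, model.length):
        d = model.length - 1 - tpos
        if not lo <= d < hi:
            continue
        gpos = model.genomic_position(tpos)
        base = contig[gpos] if model.strand == "+" else COMPLEMENT[contig[gpos]]
        prev_g = model.genomic_position(tpos - 1)
        prev = contig[prev_g] if model.strand == "+" else COMPLEMENT[contig[prev_g]]
        if base == edited and prev == truth.motif[0]:
            out.append(tpos)
    return out


@dataclass
class BulkSimulation:
    induced: list[SiteCount]
    controls: list[list[SiteCount]]
    per_gene_reads: dict[str, int]
    planted: pd.DataFrame      # gene_id, contig, position, depth, alt_count
    member_genes: set[str]     # compartment members (edited)
    unexpressed: set[str]


def simulate_bulk(
    truth: SimulationTruth,
    models: list[TranscriptModel],
    genome: dict[str, str],
    n_controls: int = 2,
) -> BulkSimulation:
    """Induced and control site-count tables plus per-gene read counts.

    Compartment-member genes carry edits at motif sites under the
    positional law, with per-read editing probability ``editing_rate``;
    cytoplasm-only genes and all controls carry only ``control_noise``.
    """
    rng = rng_for(truth.seed, "bulk")
    induced: list[SiteCount] = []
    controls: list[list[SiteCount]] = [[] for _ in range(n_controls)]
    reads: dict[str, int] = {}
    planted_rows = []
    member, unexpressed = set(), set()
    for model in models:
        gene = model.gene_id
        if rng.random() < truth.frac_unexpressed:
            unexpressed.add(gene)
            reads[gene] = 0
            continue
        depth = int(np.clip(rng.lognormal(np.log(truth.mean_depth), 0.5), 30, 5000))
        reads[gene] = depth
        is_member = rng.random() < truth.frac_compartment
        if is_member:
            member.add(gene)
        ref_t, alt_t = CHEMISTRIES[truth.chemistry]
        ref_g, alt_g = genomic_edit_bases(truth.chemistry, model.strand)
        eligible = _eligible_sites(model, genome, truth)
        n_sites = min(truth.sites_per_gene, len(eligible))
        chosen = sorted(rng.choice(eligible, size=n_sites, replace=False)) if n_sites else []
        for tpos in chosen:
            gpos = model.genomic_position(int(tpos))
            rate = truth.editing_rate if is_member else 0.0
            alt = int(rng.binomial(depth, rate)) if rate else 0
            alt = min(alt, depth)
            counts = {b: 0 for b in BASES}
            counts[ref_g] = depth - alt
            counts[alt_g] += alt
            induced.append(SiteCount(model.contig, gpos, ref_g, counts))
            for ctrl in controls:
                noise = int(rng.binomial(depth, truth.control_noise)) \
                    if truth.control_noise else 0
                ccounts = {b: 0 for b in BASES}
                ccounts[ref_g] = depth - noise
                ccounts[alt_g] += noise
                ctrl.append(SiteCount(model.contig, gpos, ref_g, ccounts))
            if is_member:
                planted_rows.append(
                    {"gene_id": gene, "contig": model.contig, "position": gpos,
                     "depth": depth, "alt_count": alt,
                     "conversion": f"{ref_t}>{alt_t}"}
                )
        # pure-reference background sites
        n_bg = min(truth.background_sites_per_gene, model.length)
        bg_tpos = rng.choice(model.length, size=n_bg, replace=False)
        chosen_set = set(int(t) for t in chosen)
        for tpos in sorted(int(t) for t in bg_tpos):
            if tpos in chosen_set:
                continue
            gpos = model.genomic_position(tpos)
            base = genome[model.contig][gpos]
            counts = {b: 0 for b in BASES}
            counts[base] = depth
            induced.append(SiteCount(model.contig, gpos, base, counts))
            for ctrl in controls:
                ctrl.append(SiteCount(model.contig, gpos, base, dict(counts)))
    planted = pd.DataFrame(
        planted_rows,
        columns=["gene_id", "contig", "position", "depth", "alt_count", "conversion"],
    )
    return BulkSimulation(
        induced=induced, controls=controls, per_gene_reads=reads,
        planted=planted, member_genes=member, unexpressed=unexpressed,
    )


def simulate_cells(
    truth: SimulationTruth,
    n_cells: int | None = None,
    seed: int | None = None,
) -> tuple[CellMatrices, dict]:
    """Paired edit-count and TPM matrices with planted heterogeneity.

    Core genes are edited (Poisson, mean ``planted_edit_mean``) in a
    ``core_cell_prob`` random subset of cells, rare genes in a
    ``rare_cell_prob`` subset; the remaining (null) genes receive each
    cell's null edit total by a TPM-proportional multinomial — exactly the
    law of the expression-matched shuffle. With ``hetero_fraction`` > 0 a
    fraction of genes is instead edited only inside a random
    ``hetero_cell_fraction`` cell subset at ``hetero_multiplier`` x weight.
    """
    n_cells = truth.n_cells if n_cells is None else n_cells
    rng = rng_for(truth.seed if seed is None else seed, "cells")
    n_genes = truth.n_genes
    genes = [f"G{g:04d}" for g in range(n_genes)]
    cells = [f"C{c:04d}" for c in range(n_cells)]

    gene_means = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    expr = gene_means[None, :] * rng.lognormal(0.0, 0.5, size=(n_cells, n_genes))
    expr = expr / expr.sum(axis=1, keepdims=True) * 1e6

    roles = np.array(["null"] * n_genes, dtype=object)
    n_core = int(round(truth.core_fraction * n_genes))
    n_rare = int(round(truth.rare_fraction * n_genes))
    n_het = int(round(truth.hetero_fraction * n_genes))
    perm = rng.permutation(n_genes)
    roles[perm[:n_core]] = "core"
    roles[perm[n_core:n_core + n_rare]] = "rare"
    roles[perm[n_core + n_rare:n_core + n_rare + n_het]] = "hetero"

    het_cells = np.zeros(n_cells, dtype=bool)
    n_het_cells = int(round(truth.hetero_cell_fraction * n_cells))
    if n_het:
        het_cells[rng.choice(n_cells, size=n_het_cells, replace=False)] = True

    edits = np.zeros((n_cells, n_genes), dtype=np.int64)
    null_mask = roles == "null"
    het_mask = roles == "hetero"
    totals = rng.poisson(truth.null_edits_per_cell, size=n_cells)
    for c in range(n_cells):
        weights = np.where(null_mask, expr[c], 0.0)
        if het_cells[c]:
            weights = weights + np.where(het_mask,
                                         expr[c] * truth.hetero_multiplier, 0.0)
        total_w = weights.sum()
        if total_w == 0:
            raise ValueError("cell has zero total weight for null edits")
        edits[c] += rng.multinomial(int(totals[c]), weights / total_w)
    for role, prob in (("core", truth.core_cell_prob), ("rare", truth.rare_cell_prob)):
        for g in np.flatnonzero(roles == role):
            hit = rng.random(n_cells) < prob
            edits[hit, g] += rng.poisson(truth.planted_edit_mean, size=int(hit.sum()))
            # planted genes must show >= min_edits signal where hit
            edits[hit, g] = np.maximum(edits[hit, g], 3)
    m = CellMatrices(cells=cells, genes=genes, edits=edits, expr=expr)
    truth_out = {
        "roles": dict(zip(genes, roles)),
        "hetero_cells": [cells[i] for i in np.flatnonzero(het_cells)],
        "null_edit_totals": totals.tolist(),
    }
    return m, truth_out


_TEMPORAL_CLASSES = ("rising", "peaked", "flat")


def _class_shape(cls: str, n_tp: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_tp)
    if cls == "rising":
        return 2.0 * t - 1.0
    if cls == "peaked":
        bump = np.exp(-((t - 0.5) ** 2) / (2 * 0.15 ** 2))
        return 2.0 * (bump - bump.min()) / (bump.max() - bump.min()) - 1.0
    return np.zeros(n_tp)


def simulate_timecourse(
    truth: SimulationTruth,
    n_genes: int | None = None,
) -> tuple[dict[str, list[GeneEditProfile]], list[GeneEditProfile], pd.Series]:
    """LI-ready edit/read profiles across timepoints.

    Rising-class genes have monotonically increasing compartment editing
    efficiency, peaked-class genes a unimodal bump, flat genes constant
    efficiency; the cytoplasmic reference is constant. Gaussian noise of SD
    ``temporal_noise_sd`` is added on the log2 LI scale. Returns
    (per-timepoint compartment profiles, cytoplasm profiles, gene classes).
    """
    rng = rng_for(truth.seed, "timecourse")
    n_genes = truth.n_genes if n_genes is None else n_genes
    n_tp = truth.n_timepoints
    genes = [f"G{g:04d}" for g in range(n_genes)]
    classes = []
    for g in range(n_genes):
        u = rng.random()
        if u < truth.frac_rising:
            classes.append("rising")
        elif u < truth.frac_rising + truth.frac_peaked:
            classes.append("peaked")
        else:
            classes.append("flat")
    timepoints = [f"t{i}" for i in range(n_tp)]
    reads = truth.timecourse_reads
    cytoplasm = [
        GeneEditProfile(gene_id=g, sample_id="cyt",
                        edit_count=int(round(truth.base_efficiency * reads)),
                        read_count=reads)
        for g in genes
    ]
    by_tp: dict[str, list[GeneEditProfile]] = {}
    for i, tp in enumerate(timepoints):
        profiles = []
        for g, cls in zip(genes, classes):
            li = truth.temporal_amplitude * _class_shape(cls, n_tp)[i]
            if truth.temporal_noise_sd:
                li += rng.normal(0.0, truth.temporal_noise_sd)
            eff = truth.base_efficiency * 2.0 ** li
            profiles.append(
                GeneEditProfile(gene_id=g, sample_id=tp,
                                edit_count=max(1, int(round(eff * reads))),
                                read_count=reads)
            )
        by_tp[tp] = profiles
    return by_tp, cytoplasm, pd.Series(classes, index=genes, name="class")


def simulate_intron_coverage(
    truth: SimulationTruth,
    model: TranscriptModel,
    n_cells_per_phase: int = 50,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell FeatureCoverage rows for every exon and intron of a model,
    with phase-dependent intron retention.

    Exon coverages are lognormal around ``flank_coverage_mean``; intron
    coverage is the flanking-exon mean times the phase's retention level
    times lognormal noise (``coverage_noise_sd`` = 0 gives exact ratios).
    """
    if len(model.exons) < 2:
        raise ValueError("model needs at least one intron")
    rng = rng_for(truth.seed, "introns")
    rows, phases = [], {}
    cell_no = 0
    for phase, retention in truth.retention_by_phase.items():
        for _ in range(n_cells_per_phase):
            cell = f"{phase}_{cell_no:04d}"
            cell_no += 1
            phases[cell] = phase
            exon_cov = [
                float(rng.lognormal(np.log(truth.flank_coverage_mean),
                                    truth.coverage_noise_sd))
                if truth.coverage_noise_sd else truth.flank_coverage_mean
                for _ in model.exons
            ]
            for k, cov in enumerate(exon_cov, start=1):
                rows.append({"cell_id": cell, "gene_id": model.gene_id,
                             "feature": f"exon_{k}", "mean_coverage": cov})
            for k in range(1, len(model.exons)):
                flank = (exon_cov[k - 1] + exon_cov[k]) / 2.0
                noise = float(rng.lognormal(0.0, truth.coverage_noise_sd)) \
                    if truth.coverage_noise_sd else 1.0
                rows.append({"cell_id": cell, "gene_id": model.gene_id,
                             "feature": f"intron_{k}",
                             "mean_coverage": flank * retention * noise})
    coverage = pd.DataFrame(rows, columns=["cell_id", "gene_id", "feature",
                                           "mean_coverage"])
    return coverage, pd.Series(phases, name="phase")
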
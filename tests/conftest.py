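import numpy as np
import pytest

from rlpkit import SimulationTruth, make_transcriptome, simulate_bulk
from rlpkit.transcript_io import SiteCount, TranscriptModel


@pytest.fixture(scope="session")
def small_transcriptome():
    models, genome = make_transcriptome(n_genes=40, seed=11)
    return models, genome


@pytest.fixture(scope="session")
def bulk_sim(small_transcriptome):
    models, genome = small_transcriptome
    truth = SimulationTruth(seed=11, n_genes=40)
    return truth, simulate_bulk(truth, models, genome)


def make_single_exon_models(n, length=500, strand_cycle=("+", "-")):
    """n single-exon genes, one per contig."""
    return [
        TranscriptModel(
            gene_id=f"g{i}", transcript_id=f"g{i}.t", contig=f"c{i}",
            strand=strand_cycle[i % len(strand_cycle)], exons=((0, length),),
        )
        for i in range(n)
    ]


def random_site_tables(rng, models, n_sites, chemistry="A>G",
                       p_missing_control=0.2, n_controls=2):
    """Random induced/control site tables over the models' exons, exercising
    every caller filter: mixed ref bases, secondary alt bases, control
    signal, and sites absent from some or all controls."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ref_t, alt_t = chemistry.split(">")
    induced, controls = [], [[] for _ in range(n_controls)]
    site_gene = {}
    used = set()
    for _ in range(n_sites):
        m = models[rng.integers(len(models))]
        pos = int(rng.integers(m.exons[0][0], m.exons[-1][1]))
        if (m.contig, pos) in used or not m.contains(pos):
            continue
        used.add((m.contig, pos))
        site_gene[(m.contig, pos)] = (m.gene_id, m.strand)
        # bias toward the chemistry's editable ref base
        if rng.random() < 0.7:
            ref = ref_t if m.strand == "+" else comp[ref_t]
        else:
            ref = "ACGT"[rng.integers(4)]
        alt = alt_t if m.strand == "+" else comp[alt_t]
        depth = int(rng.integers(5, 120))
        a = int(rng.integers(0, max(1, depth // 4)))
        second = int(rng.integers(0, 4)) if rng.random() < 0.3 else 0
        a = min(a, depth)
        second = min(second, depth - a)
        counts = {b: 0 for b in "ACGT"}
        counts[ref] = depth - a - second
        counts[alt] += a
        other = [b for b in "ACGT" if b not in (ref, alt)]
        counts[other[0]] += second
        induced.append(SiteCount(m.contig, pos, ref, counts))
        for ctrl in controls:
            if rng.random() < p_missing_control:
                continue
            ca = int(rng.integers(0, 3)) if rng.random() < 0.3 else 0
            ca = min(ca, depth)
            ccounts = {b: 0 for b in "ACGT"}
            ccounts[ref] = depth - ca
            ccounts[alt] += ca
            ctrl.append(SiteCount(m.contig, pos, ref, ccounts))
    return induced, controls, site_gene
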
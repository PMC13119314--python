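"""Reporter-induced editing-event calling.

A deaminase reporter (TadA -> A-to-I, read as A>G; APOBEC1 -> C-to-U, read
as C>T) leaves base conversions on compartment-proximal RNAs. Candidate
sites from an induced sample are compared against uninduced controls and an
event is called only if it passes four filters:

1. absent from every non-induced control (alt reads <= ``control_max_alt``);
2. a single SNV type: the chemistry's alt base carries at least
   ``purity_min_fraction`` of the non-reference reads and no other alt base
   exceeds ``max_secondary_alt`` reads;
3. supported by at least ``min_alt`` edited reads;
4. the transcript retains events only if it has at least
   ``min_events_per_transcript`` events whose editing ratio exceeds
   ``min_event_ratio``.

Conversions are reported in transcript orientation: a genomic T>C on a
``-`` strand gene is an A>G edit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections import defaultdict

import pandas as pd

from .transcript_io import BASES, SiteCount, TranscriptIndex, TranscriptModel

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: conversions in transcript orientation supported by the two chemistries
CHEMISTRIES = {"A>G": ("A", "G"), "C>T": ("C", "T")}

CONVERSION_CLASSES = [
    f"{r}>{a}" for r, a in itertools.permutations(BASES, 2)
]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the four event filters (defaults are the published ones)."""

    min_alt: int = 3
    min_events_per_transcript: int = 3
    min_event_ratio: float = 0.01
    control_max_alt: int = 0
    purity_min_fraction: float = 0.9
    #: absolute cap on reads of any secondary (non-chemistry) alt base
    max_secondary_alt: int = 2
    min_depth: int = 1
    #: policy for sites covered by no control: "reject" (default) or "accept"
    missing_control_policy: str = "reject"

    def __post_init__(self) -> None:
        if min(self.min_alt, self.min_events_per_transcript,
               self.control_max_alt, self.min_depth) < 0:
            raise ValueError("thresholds must be nonnegative")
        for frac in (self.min_event_ratio, self.purity_min_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class EditEvent:
    """One called editing site, in transcript orientation."""

    gene_id: str
    transcript_id: str
    contig: str
    position: int
    strand: str
    conversion: str
    alt_count: int
    depth: int

    @property
    def editing_ratio(self) -> float:
        return self.alt_count / self.depth


def genomic_edit_bases(chemistry: str, strand: str) -> tuple[str, str]:
    """Reference/alt bases in genome space for a chemistry on a strand."""
    ref, alt = CHEMISTRIES[chemistry]
    if strand == "+":
        return ref, alt
    return COMPLEMENT[ref], COMPLEMENT[alt]


def _site_passes(
    site: SiteCount,
    control_sites: list[SiteCount | None],
    model: TranscriptModel,
    params: CallerParams,
    chemistry: str,
) -> EditEvent | None:
    ref_g, alt_g = genomic_edit_bases(chemistry, model.strand)
    if site.ref_base != ref_g or site.depth < max(params.min_depth, 1):
        return None
    alt_count = site.counts.get(alt_g, 0)
    if alt_count < params.min_alt:
        return None
    # filter 1: absent from every control covering the site
    covered = [c for c in control_sites if c is not None]
    if not covered:
        if params.missing_control_policy != "accept":
            return None
    elif any(c.counts.get(alt_g, 0) > params.control_max_alt for c in covered):
        return None
    # filter 2: single SNV type
    nonref = {b: n for b, n in site.alt_counts.items() if n > 0}
    total_nonref = sum(nonref.values())
    if total_nonref == 0:
        return None
    if alt_count / total_nonref < params.purity_min_fraction:
        return None
    if any(n > params.max_secondary_alt for b, n in nonref.items() if b != alt_g):
        return None
    return EditEvent(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        contig=site.contig,
        position=site.position,
        strand=model.strand,
        conversion=chemistry,
        alt_count=alt_count,
        depth=site.depth,
    )


def call_events(
    induced: list[SiteCount],
    controls: list[list[SiteCount]],
    models: list[TranscriptModel] | TranscriptIndex,
    params: CallerParams = CallerParams(),
    chemistry: str = "A>G",
) -> list[EditEvent]:
    """Apply the four event filters to an induced sample against controls.

    Returns the retained events sorted by (contig, position). Sites outside
    any designated transcript, with zero depth, or (by default) covered by
    no control are skipped.
    """
    if chemistry not in CHEMISTRIES:
        raise ValueError(f"unknown chemistry {chemistry!r}")
    index = models if isinstance(models, TranscriptIndex) else TranscriptIndex(models)
    control_maps = [
        {(s.contig, s.position): s for s in ctrl} for ctrl in controls
    ]
    per_gene: dict[str, list[EditEvent]] = defaultdict(list)
    for site in induced:
        if site.depth == 0:
            continue
        model = index.lookup(site.contig, site.position)
        if model is None:
            continue
        key = (site.contig, site.position)
        ev = _site_passes(
            site, [cm.get(key) for cm in control_maps], model, params, chemistry
        )
        if ev is not None:
            per_gene[ev.gene_id].append(ev)
    # filter 4: per-transcript floor on events exceeding the ratio threshold
    kept: list[EditEvent] = []
    for gene_events in per_gene.values():
        qualifying = [
            ev for ev in gene_events if ev.editing_ratio > params.min_event_ratio
        ]
        if len(qualifying) >= params.min_events_per_transcript:
            kept.extend(qualifying)
    kept.sort(key=lambda e: (e.contig, e.position))
    return kept


def mutation_spectrum(conversions: list[str]) -> pd.Series:
    """Fractions over the 12 conversion classes for a set of candidate SNVs.

    ``conversions`` are strings like ``"A>G"`` in transcript orientation.
    """
    if not conversions:
        raise ValueError("empty candidate set")
    counts = pd.Series(0.0, index=CONVERSION_CLASSES)
    for conv in conversions:
        if conv not in counts.index:
            raise ValueError(f"unknown conversion class {conv!r}")
        counts[conv] += 1
    return counts / counts.sum()


def events_to_frame(events: list[EditEvent]) -> pd.DataFrame:
    """All EditEvent fields as a table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "transcript_id": e.transcript_id,
                "contig": e.contig,
                "position": e.position,
                "strand": e.strand,
                "conversion": e.conversion,
                "alt_count": e.alt_count,
                "depth": e.depth,
                "editing_ratio": e.editing_ratio,
            }
            for e in events
        ]
    )
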
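"""Transcript models, genome access and tabular I/O.

Coordinate conventions used throughout the package:

* every internal interval is 0-based, half-open ``[start, end)``;
* GTF input (1-based, inclusive) is converted on read;
* the poly(A) site of a transcript is the genomic coordinate of its 3'
  terminal base: ``last_exon.end - 1`` on the ``+`` strand and
  ``first_exon.start`` on the ``-`` strand.

Site-count tables are plain TSV with the columns
``contig  position  ref  A  C  G  T`` (positions 0-based), one row per
genomic site of one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

BASES = ("A", "C", "G", "T")

#: contig names treated as mitochondrial (reporting category only)
MITO_CONTIGS = {"chrM", "MT"}

SITE_COUNT_COLUMNS = ["contig", "position", "ref", "A", "C", "G", "T"]


class GTFParseError(ValueError):
    """Raised for malformed GTF input; the message names the offending line."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons on a genomic contig.

    ``exons`` are 0-based half-open intervals sorted by start and
    non-overlapping regardless of strand; transcript order (5'->3') is the
    reverse of genomic order on the ``-`` strand.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = end

    @property
    def polyA_site(self) -> int:
        """Genomic position of the transcript 3' terminal base."""
        if self.strand == "+":
            return self.exons[-1][1] - 1
        return self.exons[0][0]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order, half-open."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_transcript_order(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def contains(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)

    def transcript_position(self, position: int) -> int:
        """Map a genomic position inside an exon to a 0-based transcript
        offset from the 5' end.
        """
        offset = 0
        for s, e in self.exons_transcript_order():
            if s <= position < e:
                if self.strand == "+":
                    return offset + (position - s)
                return offset + (e - 1 - position)
            offset += e - s
        raise ValueError(
            f"position {position} not exonic in transcript {self.transcript_id}"
        )

    def genomic_position(self, tpos: int) -> int:
        """Inverse of :meth:`transcript_position`."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript offset {tpos} out of range")
        offset = 0
        for s, e in self.exons_transcript_order():
            if tpos < offset + (e - s):
                if self.strand == "+":
                    return s + (tpos - offset)
                return e - 1 - (tpos - offset)
            offset += e - s
        raise AssertionError("unreachable")

    def distance_to_polyA(self, position: int) -> int:
        """Transcript-space distance (nt) from a genomic position to the
        poly(A) site; 0 at the 3' terminal base itself.
        """
        return self.length - 1 - self.transcript_position(position)

    @property
    def is_mito(self) -> bool:
        return self.contig in MITO_CONTIGS


@dataclass(frozen=True)
class SiteCount:
    """Per-base read counts at one genomic position of one sample."""

    contig: str
    position: int
    ref_base: str
    counts: dict[str, int] = field(compare=False)
    depth: int = 0

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"unknown ref base {self.ref_base!r}")
        if any(self.counts.get(b, 0) < 0 for b in BASES):
            raise ValueError(f"negative count at {self.contig}:{self.position}")
        total = sum(self.counts.get(b, 0) for b in BASES)
        if self.depth == 0 and total:
            object.__setattr__(self, "depth", total)
        elif total != self.depth:
            raise ValueError(
                f"depth {self.depth} != base-count sum {total} at "
                f"{self.contig}:{self.position}"
            )

    @property
    def alt_counts(self) -> dict[str, int]:
        return {b: self.counts.get(b, 0) for b in BASES if b != self.ref_base}


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: bad interval {start}-{end}"
                )


_BIOTYPE_ATTRS = ("gene_type", "gene_biotype", "transcript_type", "transcript_biotype")


def _classify_biotype(raw: str | None, contig: str) -> str:
    if contig in MITO_CONTIGS:
        return "mito"
    if raw is None:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA", "antisense"):
        return "lncRNA"
    if "pseudogene" in raw:
        return "pseudogene"
    return "other"


def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into :class:`TranscriptModel` s.

    1-based inclusive GTF coordinates become 0-based half-open. Biotype is
    taken from gene/transcript type attributes when present. A transcript_id
    shared by conflicting records (different gene, contig or strand, or
    overlapping exons) is rejected.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GTFParseError(
                f"{path}: exon at {feat.seqid}:{feat.start} missing {exc} attribute"
            ) from exc
        raw_bt = None
        for attr in _BIOTYPE_ATTRS:
            if attr in feat.attributes:
                raw_bt = feat.attributes[attr][0]
                break
        rec = grouped.setdefault(
            tid, {"gene": gid, "contig": feat.seqid, "strand": feat.strand,
                  "biotype": raw_bt, "exons": []}
        )
        if (rec["gene"], rec["contig"], rec["strand"]) != (gid, feat.seqid, feat.strand):
            raise GTFParseError(
                f"{path}: duplicate transcript_id {tid!r} with conflicting records"
            )
        rec["exons"].append((feat.start - 1, feat.end))  # GTF -> half-open

    models = []
    for tid, rec in grouped.items():
        exons = sorted(rec["exons"])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GTFParseError(
                    f"{path}: duplicate transcript_id {tid!r}: overlapping exons"
                )
        models.append(
            TranscriptModel(
                gene_id=rec["gene"],
                transcript_id=tid,
                contig=rec["contig"],
                strand=rec["strand"],
                exons=tuple(exons),
                biotype=_classify_biotype(rec["biotype"], rec["contig"]),
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path: str) -> None:
    """Emit exon features (1-based inclusive coordinates) for the models."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'gene_type "{m.biotype}";'
                )
                fh.write(
                    f"{m.contig}\trlpkit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def designated_transcripts(
    models: list[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """One transcript per gene for positional analyses: the longest, ties
    broken by transcript_id.
    """
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.length > cur.length
            or (m.length == cur.length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


class TranscriptIndex:
    """Exon-interval lookup from genomic position to designated transcript."""

    def __init__(self, models: list[TranscriptModel]):
        self.by_gene = designated_transcripts(models)
        self._trees: dict[str, IntervalTree] = {}
        for m in self.by_gene.values():
            tree = self._trees.setdefault(m.contig, IntervalTree())
            for s, e in m.exons:
                tree.addi(s, e, m)

    def lookup(self, contig: str, position: int) -> TranscriptModel | None:
        tree = self._trees.get(contig)
        if tree is None:
            return None
        hits = tree[position]
        if not hits:
            return None
        # deterministic choice when designated transcripts of two genes overlap
        return min((h.data for h in hits), key=lambda m: m.transcript_id)


def read_site_counts(path: str) -> list[SiteCount]:
    """Read a TSV site-count table (header: contig position ref A C G T)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in SITE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        counts = {b: int(getattr(row, b)) for b in BASES}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"{path}: negative count at {row.contig}:{row.position}")
        if row.ref not in BASES:
            raise ValueError(f"{path}: unknown ref base {row.ref!r} at {row.contig}:{row.position}")
        out.append(
            SiteCount(
                contig=str(row.contig),
                position=int(row.position),
                ref_base=row.ref,
                counts=counts,
            )
        )
    return out


def write_site_counts(sites: list[SiteCount], path: str) -> None:
    rows = [
        {
            "contig": s.contig,
            "position": s.position,
            "ref": s.ref_base,
            **{b: s.counts.get(b, 0) for b in BASES},
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_events_bed(events, path: str) -> None:
    """BED6 for called edit events: name = gene_id:conversion,
    score = round(1000 x editing ratio)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                f"{ev.contig}\t{ev.position}\t{ev.position + 1}\t"
                f"{ev.gene_id}:{ev.conversion}\t{round(1000 * ev.editing_ratio)}\t"
                f"{ev.strand}\n"
            )


def read_fasta(path: str):
    """Indexed genome access (pyfaidx); contigs slice like strings."""
    import pyfaidx

    return pyfaidx.Fasta(path)


def read_matrix_tsv(path: str) -> pd.DataFrame:
    """Cell x gene matrix with cell ids as the index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")
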
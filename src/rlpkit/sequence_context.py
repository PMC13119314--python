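"""Strand-aware sequence context around editing sites.

Contexts are (2*flank+1)-mers centered on the edited base, read 5'->3' in
transcript orientation (minus-strand events are reverse-complemented), so
motif positions follow the field's convention: center = 0, upstream
negative. The APOBEC1 chemistry's canonical AC dinucleotide is A at -1 and
the edited C at 0; TadA's TA preference is T at -1, edited A at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .editing_caller import CHEMISTRIES, EditEvent
from .transcript_io import BASES


@dataclass
class ContextSet:
    flank: int
    sequences: list[str]
    excluded: list[EditEvent]

    def __post_init__(self) -> None:
        width = 2 * self.flank + 1
        bad = [s for s in self.sequences if len(s) != width]
        if bad:
            raise ValueError(f"context length != {width}: {bad[0]!r}")

    @property
    def freq(self) -> pd.DataFrame:
        return frequency_matrix(self)


def _fetch(genome, contig: str, start: int, end: int) -> str:
    """Slice [start, end) from a pyfaidx.Fasta or a dict of strings."""
    return str(genome[contig][start:end])


def extract_context(
    genome,
    events: list[EditEvent],
    flank: int = 10,
) -> ContextSet:
    """Extract the +/-``flank`` nt context around each event.

    ``genome`` is a pyfaidx.Fasta (or any contig -> sequence mapping).
    Events closer than ``flank`` to a contig end are excluded and reported.
    Minus-strand contexts are reverse-complemented.
    """
    sequences: list[str] = []
    excluded: list[EditEvent] = []
    for ev in events:
        contig_len = len(genome[ev.contig])
        if ev.position >= contig_len:
            raise IndexError(
                f"event position {ev.position} beyond contig {ev.contig} "
                f"length {contig_len}"
            )
        start, end = ev.position - flank, ev.position + flank + 1
        if start < 0 or end > contig_len:
            excluded.append(ev)
            continue
        seq = _fetch(genome, ev.contig, start, end).upper()
        if ev.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        sequences.append(seq)
    return ContextSet(flank=flank, sequences=sequences, excluded=excluded)


def frequency_matrix(
    contexts: ContextSet,
    background: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Position x base frequency matrix (columns A,C,G,T sum to 1 per
    position). With a background base-composition table, also returns
    log2(freq/background) enrichment columns.

    Positions are indexed -flank..flank with the edited base at 0.
    """
    if not contexts.sequences:
        raise ValueError("empty context set")
    width = 2 * contexts.flank + 1
    counts = np.zeros((width, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for seq in contexts.sequences:
        for pos, base in enumerate(seq):
            if base in base_idx:
                counts[pos, base_idx[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freq = counts / totals
    positions = np.arange(-contexts.flank, contexts.flank + 1)
    df = pd.DataFrame(freq, index=positions, columns=list(BASES))
    df.index.name = "position"
    if background is not None:
        bg = pd.Series(background, dtype=float).reindex(list(BASES))
        if bg.isna().any() or (bg <= 0).any():
            raise ValueError("background must give a positive frequency per base")
        bg = bg / bg.sum()
        with np.errstate(divide="ignore"):
            enrich = np.log2(df[list(BASES)].to_numpy() / bg.to_numpy()[None, :])
        for i, b in enumerate(BASES):
            df[f"enrichment_{b}"] = enrich[:, i]
    return df


def check_center_purity(contexts: ContextSet, chemistry: str) -> float:
    """Fraction of contexts whose center base is the chemistry's edited base."""
    edited = CHEMISTRIES[chemistry][0]
    if not contexts.sequences:
        raise ValueError("empty context set")
    center = contexts.flank
    return float(np.mean([s[center] == edited for s in contexts.sequences]))


def adenosine_content(sequences: list[str]) -> np.ndarray:
    """Per-sequence fraction of A over unambiguous bases (N excluded)."""
    out = []
    for seq in sequences:
        seq = seq.upper()
        denom = sum(seq.count(b) for b in BASES)
        if denom == 0:
            raise ValueError(f"sequence {seq!r} has no unambiguous bases")
        out.append(seq.count("A") / denom)
    return np.asarray(out)


def compare_adenosine_content(
    group_a: list[str], group_b: list[str]
) -> dict:
    """Mann-Whitney U comparison of per-sequence adenosine content."""
    a = adenosine_content(group_a)
    b = adenosine_content(group_b)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(u), "pvalue": float(p),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}
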
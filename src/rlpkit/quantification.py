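"""Gene-level editing quantification.

Definitions:

* edit count ``E_g,s`` — total editing occurrences of gene g in sample s,
  each edited read counted individually;
* ECPM — ``E_g,s / sum_i E_i,s * 1e6``, a gene's share of the sample's
  editing occurrences; deliberately not length-normalized;
* EPM — distinct editing sites per million mapped reads, a sample-level
  activity measure;
* editing efficiency — ``E_g,s / read_count_g,s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .editing_caller import EditEvent
from .transcript_io import TranscriptModel


@dataclass
class GeneEditProfile:
    gene_id: str
    sample_id: str
    edit_count: int
    read_count: int
    ecpm: float | None = None

    @property
    def efficiency(self) -> float | None:
        """Edits per mapped read; None (flagged undefined) when no reads."""
        if self.read_count == 0:
            return None
        return self.edit_count / self.read_count


def gene_edit_counts(
    events: list[EditEvent],
    per_gene_reads: dict[str, int] | pd.Series,
    sample_id: str = "sample",
) -> list[GeneEditProfile]:
    """Aggregate called events into per-gene edit totals.

    Genes present in the read table but without events get ``edit_count`` 0;
    an event whose gene is missing from the read table is an error.
    """
    reads = dict(per_gene_reads)
    totals: dict[str, int] = {g: 0 for g in reads}
    for ev in events:
        if ev.gene_id not in reads:
            raise KeyError(f"gene {ev.gene_id} absent from the read-count table")
        totals[ev.gene_id] += ev.alt_count
    return [
        GeneEditProfile(gene_id=g, sample_id=sample_id,
                        edit_count=totals[g], read_count=int(reads[g]))
        for g in sorted(reads)
    ]


def ecpm(profiles: list[GeneEditProfile]) -> list[GeneEditProfile]:
    """Fill ``ecpm`` in place: edit_count / total edits x 1e6 (no length
    normalization). Requires at least one edit in the sample."""
    total = sum(p.edit_count for p in profiles)
    if total == 0:
        raise ValueError("no edits in sample; ECPM undefined")
    for p in profiles:
        p.ecpm = p.edit_count / total * 1e6
    return profiles


def epm(total_edit_sites: int, mapped_reads: int) -> float:
    """Distinct editing sites per million mapped reads."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    return total_edit_sites / mapped_reads * 1e6


def metagene_polyA_density(
    events: list[EditEvent],
    designated: dict[str, TranscriptModel],
    window: int = 1000,
    bin_size: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Histogram of edit density over transcript-space distance upstream of
    the poly(A) site.

    Distance is measured 3'->5' in transcript coordinates (0 = the poly(A)
    site itself). Events farther than ``window`` are excluded from the
    histogram and returned as a separate count. Density sums to 1 over the
    window when any event falls inside it.
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    distances = []
    n_excluded = 0
    for ev in events:
        model = designated.get(ev.gene_id)
        if model is None:
            raise KeyError(f"no designated transcript for gene {ev.gene_id}")
        d = model.distance_to_polyA(ev.position)
        if d >= window:
            n_excluded += 1
        else:
            distances.append(d)
    edges = np.arange(0, window + bin_size, bin_size)
    counts, _ = np.histogram(distances, bins=edges)
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    df = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:],
         "count": counts, "density": density}
    )
    return df, n_excluded


def binned_expression_summary(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    n_bins: int = 10,
    min_expr: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- standard error of y in equal-width bins of x.

    ``x`` is per-gene log2 expression, ``y`` per-gene log2 ECPM. Genes with
    expression <= ``min_expr`` (on the linear scale, i.e. x <= log2(min_expr))
    are dropped first. Bins are closed on the left; the last bin is closed on
    both sides; empty bins are reported with n = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y) & (x > math.log2(min_expr))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no genes left after the expression filter")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    # right-closed last bin
    idx = np.clip(np.digitize(x, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        vals = y[idx == b]
        n = vals.size
        mean = float(vals.mean()) if n else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan)
        rows.append({"bin_left": edges[b], "bin_right": edges[b + 1],
                     "n": n, "mean": mean, "se": se})
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list[GeneEditProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": p.gene_id, "sample_id": p.sample_id,
             "edit_count": p.edit_count, "read_count": p.read_count,
             "ecpm": p.ecpm, "efficiency": p.efficiency}
            for p in profiles
        ]
    )
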
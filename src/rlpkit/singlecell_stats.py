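"""Single-cell QC and detection-rate heterogeneity statistics.

Cells carry paired matrices: integer edit counts and TPM expression
(rows ~ cells, columns ~ genes; TPM rows sum to 1e6). QC removes cells with
too few detected genes and editing-activity outliers. A gene's detection
rate is the fraction of passing cells in which it accumulates at least
``min_edits`` (default 3) edits. Observed detection-rate histograms are
compared against an expression-matched null in which each cell's edit total
is randomly reassigned across genes with probability proportional to TPM,
via a chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TPM_TOTAL = 1e6
TPM_TOL = 0.01  # relative tolerance on per-cell TPM sums


@dataclass
class CellMatrices:
    """Paired cell x gene edit-count and TPM matrices."""

    cells: list[str]
    genes: list[str]
    edits: np.ndarray
    expr: np.ndarray
    phase: list[str] | None = None

    def __post_init__(self) -> None:
        self.edits = np.asarray(self.edits)
        self.expr = np.asarray(self.expr, dtype=float)
        shape = (len(self.cells), len(self.genes))
        if self.edits.shape != shape or self.expr.shape != shape:
            raise ValueError("matrix dimensions do not match cell/gene ids")
        if np.any(self.edits < 0) or not np.issubdtype(self.edits.dtype, np.integer):
            raise ValueError("edit counts must be nonnegative integers")
        sums = self.expr.sum(axis=1)
        bad = np.abs(sums - TPM_TOTAL) > TPM_TOL * TPM_TOTAL
        if np.any(bad):
            raise ValueError(
                f"TPM rows must sum to 1e6 (+/-1%); offending cells: "
                f"{[self.cells[i] for i in np.flatnonzero(bad)[:5]]}"
            )
        if self.phase is not None and len(self.phase) != len(self.cells):
            raise ValueError("phase labels must match cells")

    def subset_cells(self, keep: np.ndarray) -> "CellMatrices":
        idx = np.flatnonzero(keep)
        return CellMatrices(
            cells=[self.cells[i] for i in idx],
            genes=list(self.genes),
            edits=self.edits[idx],
            expr=self.expr[idx],
            phase=[self.phase[i] for i in idx] if self.phase is not None else None,
        )


@dataclass
class CellQCRecord:
    cell_id: str
    detected_genes: int
    edited_genes: int
    total_edits: int
    editing_ratio: float | None
    passed: bool
    reason: str = ""


@dataclass
class DetectionRateResult:
    rates: pd.Series                 # per-gene detection rate (passing cells)
    bin_edges: np.ndarray
    observed: np.ndarray             # genes per 10% bin (rate-0 genes excluded)
    n_zero_rate: int
    shuffled_mean: np.ndarray
    shuffled_sd: np.ndarray
    chi2: float
    df: int
    pvalue: float
    merged_bins: list[int] = field(default_factory=list)


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    """Q1/Q3 by linear interpolation (the type-7 convention)."""
    return (
        float(np.quantile(values, 0.25)),
        float(np.quantile(values, 0.75)),
    )


def qc_filter_cells(
    m: CellMatrices,
    mode: str,
    min_genes: int = 9000,
    min_edits_per_gene: int = 3,
    editing_ratio: np.ndarray | None = None,
    read_support: np.ndarray | None = None,
    min_support_reads: int = 5,
    min_support_cells: int = 2,
    iqr_factor_nes: float = 1.5,
    erm_min_edited_genes: int = 200,
    iqr_factor_erm: float = 3.0,
) -> tuple[CellMatrices, list[CellQCRecord]]:
    """Three-step cell QC.

    1. Genes retained only if supported by >= ``min_support_reads`` reads in
       >= ``min_support_cells`` cells (needs ``read_support``; skipped when
       the gene set is pre-filtered and no support matrix is given).
    2. Cells with fewer than ``min_genes`` detected genes (TPM > 0 after
       gene retention) removed.
    3. mode "NES": cells outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] on edited-gene
       count — and on editing ratio, when provided — removed.
       mode "ERM": cells with edited genes < 200 or > Q3 + 3 IQR removed.
       Fences are inclusive: a cell exactly on a fence is kept. Fewer than 4
       cells surviving to this step is an error (quartiles unstable).
    """
    if mode not in ("NES", "ERM"):
        raise ValueError(f"unknown QC mode {mode!r}")
    work = m
    if read_support is not None:
        support = np.asarray(read_support)
        if support.shape != work.edits.shape:
            raise ValueError("read_support shape must match the matrices")
        keep_genes = (support >= min_support_reads).sum(axis=0) >= min_support_cells
        idx = np.flatnonzero(keep_genes)
        expr = work.expr[:, idx]
        scale = expr.sum(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        work = CellMatrices(
            cells=list(work.cells),
            genes=[work.genes[i] for i in idx],
            edits=work.edits[:, idx],
            expr=expr / scale * TPM_TOTAL,
            phase=work.phase,
        )

    detected = (work.expr > 0).sum(axis=1)
    edited = (work.edits >= min_edits_per_gene).sum(axis=1)
    totals = work.edits.sum(axis=1)
    er = np.asarray(editing_ratio, dtype=float) if editing_ratio is not None else None
    if er is not None and er.shape[0] != len(work.cells):
        raise ValueError("editing_ratio must have one value per cell")

    records = [
        CellQCRecord(
            cell_id=c, detected_genes=int(detected[i]), edited_genes=int(edited[i]),
            total_edits=int(totals[i]),
            editing_ratio=float(er[i]) if er is not None else None,
            passed=True,
        )
        for i, c in enumerate(work.cells)
    ]
    alive = detected >= min_genes
    for i in np.flatnonzero(~alive):
        records[i].passed, records[i].reason = False, "min_genes"

    if alive.sum() < 4:
        raise ValueError("fewer than 4 cells survive to the IQR step; quartiles unstable")

    def fence_out(values: np.ndarray, factor: float, lower: bool) -> np.ndarray:
        q1, q3 = _quartiles(values[alive])
        iqr = q3 - q1
        out = values > q3 + factor * iqr
        if lower:
            out |= values < q1 - factor * iqr
        return out

    if mode == "NES":
        out = fence_out(edited.astype(float), iqr_factor_nes, lower=True)
        reason = np.where(out, "edited_genes_outlier", "")
        if er is not None:
            out_er = fence_out(er, iqr_factor_nes, lower=True)
            reason = np.where(out_er & ~out, "editing_ratio_outlier", reason)
            out |= out_er
    else:  # ERM
        floor = edited < erm_min_edited_genes
        high = fence_out(edited.astype(float), iqr_factor_erm, lower=False)
        out = floor | high
        reason = np.where(floor, "min_edited_genes",
                          np.where(high, "edited_genes_outlier", ""))
    for i in np.flatnonzero(alive & out):
        records[i].passed, records[i].reason = False, str(reason[i])
    alive &= ~out
    return work.subset_cells(alive), records


def detection_rates(m: CellMatrices, min_edits: int = 3) -> pd.Series:
    """Per-gene fraction of cells carrying >= ``min_edits`` edits."""
    if len(m.cells) == 0:
        raise ValueError("no cells")
    frac = (m.edits >= min_edits).mean(axis=0)
    return pd.Series(frac, index=m.genes, name="detection_rate")


def bin_rates(rates: pd.Series | np.ndarray, width: float = 0.1) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of nonzero detection rates in 10% bins.

    Bins are [0,0.1), ..., [0.9,1.0] (top closed). Genes with rate 0 are
    excluded from the histogram; their count is returned separately.
    Returns (bin_edges, counts, n_zero_rate).
    """
    values = np.asarray(rates, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("rates must lie in [0, 1]")
    nonzero = values[values > 0]
    n_bins = int(round(1 / width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(nonzero, edges[1:-1], right=False), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts, int((values == 0).sum())


def shuffle_null(
    m: CellMatrices,
    n_shuffles: int = 3,
    min_edits: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Expression-matched null for the detection-rate histogram.

    Per shuffle and per cell, the cell's observed edit total is reassigned
    across genes by a multinomial with probabilities proportional to the
    cell's TPM row. Genes accumulating >= ``min_edits`` simulated edits in
    at least one cell are retained; detection rates are computed over all
    cells and binned as in :func:`bin_rates`. Returns (per-bin mean, per-bin
    SD over shuffles, the per-shuffle histograms).
    """
    row_sums = m.expr.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(f"cell {m.cells[zero[0]]} has zero total TPM")
    totals = m.edits.sum(axis=1)
    probs = m.expr / row_sums[:, None]
    root = np.random.SeedSequence(seed)
    histograms = []
    for child in root.spawn(n_shuffles):
        rng = np.random.default_rng(child)
        sim = np.vstack(
            [rng.multinomial(int(totals[c]), probs[c]) for c in range(len(m.cells))]
        )
        retained = (sim >= min_edits).any(axis=0)
        rates = (sim[:, retained] >= min_edits).mean(axis=0)
        _, counts, _ = bin_rates(rates)
        histograms.append(counts)
    stacked = np.vstack(histograms)
    return stacked.mean(axis=0), stacked.std(axis=0, ddof=0), histograms


def chisq_gof(
    observed: np.ndarray,
    expected: np.ndarray,
    min_expected: float = 5.0,
) -> tuple[float, int, float, list[int]]:
    """Chi-square goodness of fit of observed bin counts against expected.

    Expected counts are rescaled so their total matches the observed total;
    bins with expected < ``min_expected`` are merged rightward (the last bin
    leftward). Returns (statistic, df, p, indices of merged source bins).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if exp.sum() <= 0:
        raise ValueError("expected distribution is empty")
    exp = exp * obs.sum() / exp.sum()
    merged: list[int] = []
    o, e = list(obs), list(exp)
    i = 0
    while i < len(e):
        if e[i] < min_expected and len(e) > 1:
            j = i + 1 if i + 1 < len(e) else i - 1
            e[j] += e[i]
            o[j] += o[i]
            del e[i], o[i]
            merged.append(i)
            if j < i:
                i -= 1
        else:
            i += 1
    o_arr, e_arr = np.asarray(o), np.asarray(e)
    if len(e_arr) < 2:
        # everything collapsed into one bin: no df left to test
        return 0.0, 0, 1.0, merged
    stat = float(((o_arr - e_arr) ** 2 / e_arr).sum())
    df = len(e_arr) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p, merged


def detection_rate_analysis(
    m: CellMatrices,
    n_shuffles: int = 3,
    min_edits: int = 3,
    seed: int = 0,
) -> DetectionRateResult:
    """Observed detection-rate histogram, shuffled null, and chi-square test."""
    rates = detection_rates(m, min_edits=min_edits)
    edges, observed, n_zero = bin_rates(rates)
    mean, sd, _ = shuffle_null(m, n_shuffles=n_shuffles, min_edits=min_edits, seed=seed)
    stat, df, p, merged = chisq_gof(observed, mean)
    return DetectionRateResult(
        rates=rates, bin_edges=edges, observed=observed, n_zero_rate=n_zero,
        shuffled_mean=mean, shuffled_sd=sd, chi2=stat, df=df, pvalue=p,
        merged_bins=merged,
    )


def occurrence_overlap(
    rates: pd.Series, bulk_genes: set[str], width: float = 0.1
) -> pd.DataFrame:
    """Per detection-rate bin, the fraction of genes also found in a bulk
    experiment's detected set."""
    values = rates[rates > 0]
    n_bins = int(round(1 / width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(values.to_numpy(), edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        genes = values.index[idx == b]
        n = len(genes)
        overlap = sum(g in bulk_genes for g in genes)
        rows.append(
            {"bin_start": edges[b], "bin_end": edges[b + 1], "n_genes": n,
             "n_overlap": overlap,
             "fraction_overlap": overlap / n if n else np.nan}
        )
    return pd.DataFrame(rows)
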
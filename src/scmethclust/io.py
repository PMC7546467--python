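"""Reading per-cell methylation calls, assembling the cell x CpG matrix,
and the region filtering / selection rules used before clustering.

Two call-file dialects are supported:

* ``bismark_cov`` — the 6-column Bismark coverage format
  (chrom, start, end, methylation percentage, count methylated,
  count unmethylated);
* ``simple_tsv`` — 4 columns: chrom, pos, methylation fraction, coverage.

Fractional calls are binarized at 0.5 (inclusive: a fraction of exactly
0.5 is called methylated).  Region filtering follows the coverage rules
commonly applied to sc-WGBS region matrices: drop regions empty in every
cell, drop regions whose mean missing proportion is >= 95%, and keep a
region only if at least 5% of its CpGs are observed in all cells (strict
mode) or in at least 10% of cells (default mode).  The most variable
regions are then selected by the interquartile range (IQR) of per-cell
region mean methylation, optionally targeting a total CpG count.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .matrix import MISSING, BulkProfile, CellMethylationMatrix, MethylationCall, RegionSet

logger = logging.getLogger(__name__)

DIALECTS = ("bismark_cov", "simple_tsv")


class ParseError(ValueError):
    """A call file row that does not match the declared dialect."""


class EmptyResultError(ValueError):
    """A filter or matrix build that removed everything."""


# ----------------------------------------------------------------------
# call files
# ----------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_methylation_calls(path, dialect: str = "bismark_cov") -> list[MethylationCall]:
    """Parse a per-cell methylation call file into a list of calls.

    Raises :class:`ParseError` naming the offending line on malformed rows.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    calls: list[MethylationCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bismark_cov":
                    if len(fields) != 6:
                        raise ValueError(f"expected 6 columns, got {len(fields)}")
                    chrom, start, _end, _pct, n_meth, n_unmeth = fields
                    n_meth, n_unmeth = int(n_meth), int(n_unmeth)
                    cov = n_meth + n_unmeth
                    frac = n_meth / cov if cov > 0 else 0.0
                    calls.append(MethylationCall(chrom, int(start), frac, cov))
                else:
                    if len(fields) != 4:
                        raise ValueError(f"expected 4 columns, got {len(fields)}")
                    chrom, pos, frac, cov = fields
                    calls.append(
                        MethylationCall(chrom, int(pos), float(frac), int(cov))
                    )
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return calls


def binarize(call: MethylationCall) -> int:
    """Binary methylation state of a call: 1 iff meth_fraction >= 0.5."""
    return 1 if call.meth_fraction >= 0.5 else 0


def merge_duplicate_calls(calls: Iterable[MethylationCall]) -> list[MethylationCall]:
    """Merge calls at the same (chrom, pos) by summing read counts.

    The merged fraction is the coverage-weighted mean; zero-coverage calls
    merge by simple averaging of fractions.
    """
    acc: dict[tuple[str, int], list[float]] = {}
    for c in calls:
        key = (c.chrom, c.pos)
        if key not in acc:
            acc[key] = [0.0, 0, 0]  # weighted meth reads, coverage, n calls
        a = acc[key]
        a[0] += c.meth_fraction * max(c.coverage, 1)
        a[1] += c.coverage
        a[2] += max(c.coverage, 1)
        acc[key] = a
    out = []
    for (chrom, pos), (wmeth, cov, denom) in sorted(acc.items()):
        frac = wmeth / denom if denom else 0.0
        out.append(MethylationCall(chrom, pos, min(frac, 1.0), cov))
    return out


# ----------------------------------------------------------------------
# matrix assembly
# ----------------------------------------------------------------------

def build_matrix(
    cells: Sequence[tuple[str, Sequence[tuple[MethylationCall, int]]]],
    regions: RegionSet,
    cpg_catalog: Sequence[tuple[str, int]] | None = None,
) -> CellMethylationMatrix:
    """Assemble the ternary cell x CpG matrix over catalog CpGs in regions.

    Parameters
    ----------
    cells : sequence of (cell_id, [(call, state), ...])
        Binarized calls per cell.
    regions : RegionSet
        Regions of interest; calls outside every region are dropped.
    cpg_catalog : optional list of (chrom, pos)
        Candidate CpG coordinates.  Defaults to the union of observed
        positions across cells.

    A catalog CpG at 1-based position ``pos`` belongs to a BED region
    ``[start, end)`` iff ``start <= pos - 1 < end``.  Regions containing no
    catalog CpG do not appear in the matrix.
    """
    if cpg_catalog is None:
        seen = set()
        for _cid, pairs in cells:
            for call, _state in pairs:
                seen.add((call.chrom, call.pos))
        cpg_catalog = sorted(seen)

    reg_df = regions.df
    # assign each catalog CpG to its containing region, if any
    cols: list[tuple[str, int, str]] = []  # chrom, pos, region_id
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values("start") for c, g in reg_df.groupby("chrom")
    }
    for chrom, pos in sorted(cpg_catalog):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        zero = pos - 1
        i = np.searchsorted(sub["start"].to_numpy(), zero, side="right") - 1
        if i >= 0 and zero < sub.iloc[i]["end"]:
            cols.append((chrom, pos, sub.iloc[i]["id"]))
    if not cols:
        raise EmptyResultError("no catalog CpG falls inside any region")

    # order columns by region (chrom, start) order then position
    order_of = {rid: i for i, rid in enumerate(reg_df["id"])}
    cols.sort(key=lambda c: (order_of[c[2]], c[0], c[1]))
    col_of = {(c, p): j for j, (c, p, _r) in enumerate(cols)}

    region_ids = []
    region_index = np.empty(len(cols), dtype=np.int64)
    for j, (_c, _p, rid) in enumerate(cols):
        if not region_ids or region_ids[-1] != rid:
            region_ids.append(rid)
        region_index[j] = len(region_ids) - 1

    values = np.full((len(cells), len(cols)), MISSING, dtype=np.int8)
    cell_ids = []
    for i, (cid, pairs) in enumerate(cells):
        cell_ids.append(cid)
        for call, state in pairs:
            j = col_of.get((call.chrom, call.pos))
            if j is not None:
                values[i, j] = state
    return CellMethylationMatrix(
        cell_ids=cell_ids,
        cpg_chrom=np.array([c for c, _p, _r in cols], dtype=object),
        cpg_pos=np.array([p for _c, p, _r in cols]),
        region_index=region_index,
        region_ids=region_ids,
        values=values,
        regions=regions.subset(region_ids),
    )


# ----------------------------------------------------------------------
# region filtering / selection
# ----------------------------------------------------------------------

def filter_regions(
    matrix: CellMethylationMatrix,
    mode: str = "frac_cells",
    min_region_coverage: float = 0.05,
    min_cell_frac: float = 0.10,
    max_mean_missing: float = 0.95,
) -> RegionSet | list[str]:
    """Apply the coverage-based region filters; returns kept region ids.

    Three filters in order: (1) drop regions with zero observations in
    every cell; (2) drop regions whose mean missing proportion across cells
    is >= ``max_mean_missing``; (3) keep a region iff the fraction of its
    CpGs observed is >= ``min_region_coverage`` in all cells
    (``mode='all_cells'``) or in >= ``min_cell_frac`` of cells
    (``mode='frac_cells'``).
    """
    if mode not in ("all_cells", "frac_cells"):
        raise ValueError(f"unknown mode {mode!r}")
    obs = matrix.observed  # N x M
    sizes = matrix.region_sizes.astype(float)
    R = matrix.n_regions
    # per-cell observed-CpG count per region: N x R
    obs_per_region = np.zeros((matrix.n_cells, R))
    np.add.at(obs_per_region.T, matrix.region_index, obs.T.astype(float))
    cover_frac = obs_per_region / sizes  # N x R fraction of region CpGs observed

    n_removed = {"empty": 0, "missing": 0, "coverage": 0}
    keep = np.ones(R, dtype=bool)

    empty = obs_per_region.sum(axis=0) == 0
    n_removed["empty"] = int(empty.sum())
    keep &= ~empty

    mean_missing = 1.0 - cover_frac.mean(axis=0)
    high_missing = keep & (mean_missing >= max_mean_missing)
    n_removed["missing"] = int(high_missing.sum())
    keep &= ~high_missing

    if mode == "all_cells":
        ok = (cover_frac >= min_region_coverage).all(axis=0)
    else:
        frac_ok = (cover_frac >= min_region_coverage).mean(axis=0)
        ok = frac_ok >= min_cell_frac
    low = keep & ~ok
    n_removed["coverage"] = int(low.sum())
    keep &= ok

    if not keep.any():
        raise EmptyResultError(
            f"all regions removed (empty: {n_removed['empty']}, "
            f">=95% missing: {n_removed['missing']}, "
            f"low coverage: {n_removed['coverage']})"
        )
    kept_ids = [matrix.region_ids[i] for i in np.where(keep)[0]]
    if matrix.regions is not None:
        return matrix.regions.subset(kept_ids)
    return kept_ids


def region_means(matrix: CellMethylationMatrix) -> pd.DataFrame:
    """Per-cell mean methylation of each region (NaN where no data).

    Returns an N x R DataFrame indexed by cell id with region-id columns.
    """
    obs = matrix.observed
    vals = np.where(obs, matrix.values, 0).astype(float)
    R = matrix.n_regions
    sums = np.zeros((matrix.n_cells, R))
    counts = np.zeros((matrix.n_cells, R))
    np.add.at(sums.T, matrix.region_index, vals.T)
    np.add.at(counts.T, matrix.region_index, obs.T.astype(float))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(means, index=matrix.cell_ids, columns=matrix.region_ids)


def _region_iqr(matrix: CellMethylationMatrix) -> pd.Series:
    """IQR of per-cell region mean methylation, over cells with data."""
    means = region_means(matrix)
    q3 = means.quantile(0.75, axis=0)
    q1 = means.quantile(0.25, axis=0)
    return (q3 - q1).fillna(0.0)


def select_regions_iqr(
    matrix: CellMethylationMatrix,
    target_loci: int | None = None,
    min_iqr: float | None = None,
) -> RegionSet | list[str]:
    """Select the most variable regions by IQR of region mean methylation.

    Exactly one of ``target_loci`` / ``min_iqr`` must be given.  With
    ``min_iqr``, regions with IQR >= threshold are kept.  With
    ``target_loci``, regions are ranked by IQR descending (ties broken by
    larger region, then (chrom, start) order) and the shortest prefix whose
    cumulative CpG count reaches the target is kept.
    """
    if (target_loci is None) == (min_iqr is None):
        raise ValueError("supply exactly one of target_loci / min_iqr")
    iqr = _region_iqr(matrix)
    sizes = pd.Series(matrix.region_sizes, index=matrix.region_ids)

    if min_iqr is not None:
        kept = [rid for rid in matrix.region_ids if iqr[rid] >= min_iqr]
        if not kept:
            raise EmptyResultError(f"no region has IQR >= {min_iqr}")
    else:
        order = sorted(
            range(len(matrix.region_ids)),
            key=lambda i: (-iqr.iloc[i], -sizes.iloc[i], i),
        )
        kept, cum = [], 0
        for i in order:
            kept.append(matrix.region_ids[i])
            cum += int(sizes.iloc[i])
            if cum >= target_loci:
                break
        if cum < target_loci:
            logger.warning(
                "only %d loci available; target was %d", cum, target_loci
            )
        if not kept:
            raise EmptyResultError("no regions available for IQR selection")
        # restore genomic order for the output set
        kept = [rid for rid in matrix.region_ids if rid in set(kept)]
    if matrix.regions is not None:
        return matrix.regions.subset(kept)
    return kept


# ----------------------------------------------------------------------
# differential methylation between two bulks
# ----------------------------------------------------------------------

def dmr_fisher(
    bulk_a: BulkProfile,
    bulk_b: BulkProfile,
    regions: RegionSet,
    min_coverage: int = 5,
    fdr: float = 0.05,
    return_table: bool = False,
):
    """Differentially methylated regions between two bulk profiles.

    Counts are pooled per region; each region with total coverage >=
    ``min_coverage`` in both samples gets a two-sided Fisher's exact test
    on the 2x2 (methylated, unmethylated) x (A, B) table; regions with
    Benjamini-Hochberg adjusted p <= ``fdr`` are retained.  With
    ``return_table`` the per-region test table (counts, p, adjusted p,
    kept flag) is returned alongside the RegionSet.
    """

    def pooled(bulk: BulkProfile) -> dict[str, tuple[int, int]]:
        out: dict[str, list[int]] = {}
        by_chrom = {c: g.sort_values("start") for c, g in regions.df.groupby("chrom")}
        for chrom, pos, meth, total in zip(bulk.chrom, bulk.pos, bulk.meth, bulk.total):
            sub = by_chrom.get(chrom)
            if sub is None:
                continue
            zero = pos - 1
            i = np.searchsorted(sub["start"].to_numpy(), zero, side="right") - 1
            if i >= 0 and zero < sub.iloc[i]["end"]:
                rid = sub.iloc[i]["id"]
                acc = out.setdefault(rid, [0, 0])
                acc[0] += int(meth)
                acc[1] += int(total)
        return {rid: (m, t) for rid, (m, t) in out.items()}

    counts_a, counts_b = pooled(bulk_a), pooled(bulk_b)
    rows = []
    for rid in regions.ids:
        if rid not in counts_a or rid not in counts_b:
            continue
        ma, ta = counts_a[rid]
        mb, tb = counts_b[rid]
        if ta < min_coverage or tb < min_coverage:
            continue
        table = [[ma, ta - ma], [mb, tb - mb]]
        _odds, p = fisher_exact(table, alternative="two-sided")
        rows.append({"id": rid, "meth_a": ma, "total_a": ta,
                     "meth_b": mb, "total_b": tb, "p": p})
    if not rows:
        result = regions.subset([])
        if return_table:
            return result, pd.DataFrame(
                columns=["id", "meth_a", "total_a", "meth_b", "total_b",
                         "p", "p_adj", "kept"]
            )
        return result
    table_df = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table_df["p"], alpha=fdr, method="fdr_bh")
    table_df["p_adj"] = p_adj
    table_df["kept"] = reject
    kept = table_df.loc[table_df["kept"], "id"].tolist()
    result = regions.subset(kept)
    if return_table:
        return result, table_df
    return result


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def save_matrix(matrix: CellMethylationMatrix, prefix) -> None:
    """Write a matrix as <prefix>_matrix.tsv.gz (long form: cell_id,
    cpg_index, value) plus <prefix>_cpgs.tsv column metadata."""
    prefix = str(prefix)
    rows, cols = np.where(matrix.observed)
    long = pd.DataFrame(
        {
            "cell_id": [matrix.cell_ids[i] for i in rows],
            "cpg_index": cols,
            "value": matrix.values[rows, cols],
        }
    )
    long.to_csv(prefix + "_matrix.tsv.gz", sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "cpg_index": np.arange(matrix.n_cpgs),
            "chrom": matrix.cpg_chrom,
            "pos": matrix.cpg_pos,
            "region_id": [matrix.region_ids[r] for r in matrix.region_index],
        }
    )
    meta.to_csv(prefix + "_cpgs.tsv", sep="\t", index=False)
    with open(prefix + "_cells.tsv", "w") as fh:
        fh.write("cell_id\n")
        for cid in matrix.cell_ids:
            fh.write(f"{cid}\n")


def load_matrix(prefix) -> CellMethylationMatrix:
    """Load a matrix written by :func:`save_matrix`."""
    prefix = str(prefix)
    meta = pd.read_csv(prefix + "_cpgs.tsv", sep="\t")
    cells = pd.read_csv(prefix + "_cells.tsv", sep="\t")["cell_id"].astype(str).tolist()
    long = pd.read_csv(prefix + "_matrix.tsv.gz", sep="\t")
    long["cell_id"] = long["cell_id"].astype(str)
    region_ids = list(dict.fromkeys(meta["region_id"]))
    code = {rid: i for i, rid in enumerate(region_ids)}
    values = np.full((len(cells), len(meta)), MISSING, dtype=np.int8)
    row_of = {cid: i for i, cid in enumerate(cells)}
    values[
        [row_of[c] for c in long["cell_id"]],
        long["cpg_index"].to_numpy(),
    ] = long["value"].to_numpy()
    return CellMethylationMatrix(
        cell_ids=cells,
        cpg_chrom=meta["chrom"].to_numpy(dtype=object),
        cpg_pos=meta["pos"].to_numpy(),
        region_index=np.array([code[r] for r in meta["region_id"]]),
        region_ids=region_ids,
        values=values,
    )


def read_regions_bed(path) -> RegionSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "id"][: _bed_ncols(path)],
    )
    if "id" not in df.columns:
        df["id"] = None
    return RegionSet(df.itertuples(index=False))


def _bed_ncols(path) -> int:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.split("\t")), 4)
    return 3


def write_regions_bed(regions: RegionSet, path) -> None:
    regions.df.to_csv(path, sep="\t", header=False, index=False)


def read_bulk_tsv(path) -> BulkProfile:
    """Bulk TSV: chrom, pos, meth_count, total_count (no header or header)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["chrom", "pos"]:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "pos", "meth_count", "total_count"],
        )
    return BulkProfile(
        chrom=df.iloc[:, 0].to_numpy(dtype=object),
        pos=df.iloc[:, 1].to_numpy(),
        meth=df.iloc[:, 2].to_numpy(),
        total=df.iloc[:, 3].to_numpy(),
    )


def write_bulk_tsv(bulk: BulkProfile, path) -> None:
    pd.DataFrame(
        {
            "chrom": bulk.chrom,
            "pos": bulk.pos,
            "meth_count": bulk.meth,
            "total_count": bulk.total,
        }
    ).to_csv(path, sep="\t", index=False)
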
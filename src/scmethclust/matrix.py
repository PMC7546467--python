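"""Core containers: methylation calls, genomic region sets and the sparse
cell x CpG methylation matrix.

The matrix is ternary: each entry is 0 (unmethylated), 1 (methylated) or
missing.  Internally it is stored dense as ``int8`` with ``-1`` marking a
missing call; sc-WGBS matrices after region selection are small enough
(hundreds of cells x tens of thousands of CpGs) that a dense array with a
mask is both simpler and faster than a scipy sparse structure, which cannot
distinguish an explicit 0 from an absent entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class MethylationCall:
    """A single CpG methylation call in one cell.

    ``pos`` is the 1-based coordinate of the forward-strand C of the CpG.
    """

    chrom: str
    pos: int
    meth_fraction: float
    coverage: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise ValueError(
                f"meth_fraction must be in [0, 1], got {self.meth_fraction}"
            )
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


class RegionSet:
    """An ordered set of genomic regions in BED convention.

    Coordinates are 0-based half-open ``[start, end)``.  Regions are kept in
    a deterministic (chrom, start) order and must be non-overlapping within
    a chromosome.
    """

    def __init__(self, regions: Iterable[tuple]) -> None:
        rows = []
        for reg in regions:
            chrom, start, end = reg[0], int(reg[1]), int(reg[2])
            rid = reg[3] if len(reg) > 3 and reg[3] is not None else None
            if start >= end:
                raise ValueError(f"region {chrom}:{start}-{end} has start >= end")
            if rid is None:
                rid = f"{chrom}:{start}-{end}"
            rows.append((str(chrom), start, end, str(rid)))
        rows.sort(key=lambda r: (r[0], r[1]))
        prev = {}
        for chrom, start, end, rid in rows:
            if chrom in prev and start < prev[chrom]:
                raise ValueError(f"overlapping regions on {chrom} near {start}")
            prev[chrom] = end
        self._df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionSet":
        cols = [df["chrom"], df["start"], df["end"]]
        ids = df["id"] if "id" in df.columns else [None] * len(df)
        return cls(zip(*cols, ids))

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def ids(self) -> list[str]:
        return list(self._df["id"])

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        return iter(self._df.itertuples(index=False, name="Region"))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._df.equals(other._df)

    def subset(self, ids: Sequence[str]) -> "RegionSet":
        keep = set(ids)
        sub = self._df[self._df["id"].isin(keep)]
        return RegionSet.from_dataframe(sub)

    def contains(self, chrom: str, pos: int) -> str | None:
        """Region id containing the 1-based CpG position, or None."""
        zero = pos - 1
        sub = self._df[self._df["chrom"] == chrom]
        hit = sub[(sub["start"] <= zero) & (zero < sub["end"])]
        if len(hit) == 0:
            return None
        return hit.iloc[0]["id"]

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} regions)"


@dataclass
class CellMethylationMatrix:
    """Ternary N x M cell-by-CpG matrix with a region index.

    Attributes
    ----------
    cell_ids : list of str
        Row identifiers, length N.
    cpg_chrom, cpg_pos : arrays of length M
        Genomic coordinate of each CpG column (1-based position).
    region_index : int array of length M
        Column -> region code in ``0 .. R-1``; columns of a region are
        contiguous and regions appear in (chrom, start) order.
    region_ids : list of str, length R
        Region identifier per region code.
    values : int8 array (N, M)
        0 / 1 observed states, -1 for missing.
    """

    cell_ids: list[str]
    cpg_chrom: np.ndarray
    cpg_pos: np.ndarray
    region_index: np.ndarray
    region_ids: list[str]
    values: np.ndarray
    regions: RegionSet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.region_index = np.asarray(self.region_index, dtype=np.int64)
        self.cpg_pos = np.asarray(self.cpg_pos, dtype=np.int64)
        self.cpg_chrom = np.asarray(self.cpg_chrom, dtype=object)
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.cpg_pos) != m or len(self.region_index) != m:
            raise ValueError("column metadata length does not match matrix")
        obs = self.values[self.values != MISSING]
        if obs.size and not np.isin(obs, [0, 1]).all():
            raise ValueError("observed entries must be 0 or 1")
        if m and self.region_index.max() + 1 != len(self.region_ids):
            raise ValueError("region_ids does not cover region_index codes")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed entries."""
        return self.values != MISSING

    @property
    def region_sizes(self) -> np.ndarray:
        """Number of CpG columns per region (L_r)."""
        return np.bincount(self.region_index, minlength=self.n_regions)

    def missing_fraction(self) -> float:
        return float((self.values == MISSING).mean())

    def select_columns(self, cols: np.ndarray) -> "CellMethylationMatrix":
        """Subset to the given columns, re-coding regions consecutively."""
        cols = np.asarray(cols)
        ridx = self.region_index[cols]
        codes, new_idx = np.unique(ridx, return_inverse=True)
        return CellMethylationMatrix(
            cell_ids=list(self.cell_ids),
            cpg_chrom=self.cpg_chrom[cols],
            cpg_pos=self.cpg_pos[cols],
            region_index=new_idx,
            region_ids=[self.region_ids[c] for c in codes],
            values=self.values[:, cols],
            regions=self.regions,
        )

    def subset_regions(self, region_ids: Sequence[str]) -> "CellMethylationMatrix":
        keep = set(region_ids)
        codes = [i for i, rid in enumerate(self.region_ids) if rid in keep]
        cols = np.where(np.isin(self.region_index, codes))[0]
        if cols.size == 0:
            raise ValueError("no columns left after region subset")
        return self.select_columns(cols)

    def __repr__(self) -> str:
        return (
            f"CellMethylationMatrix({self.n_cells} cells x {self.n_cpgs} CpGs, "
            f"{self.n_regions} regions, "
            f"{self.missing_fraction():.1%} missing)"
        )


@dataclass
class BulkProfile:
    """Per-CpG methylated / total read counts from a bulk experiment.

    ``total`` may be a scalar depth D shared by all CpGs or a per-CpG array.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.broadcast_to(
            np.asarray(self.total, dtype=np.int64), self.meth.shape
        ).copy()
        self.chrom = np.asarray(self.chrom, dtype=object)
        if ((self.meth < 0) | (self.meth > self.total)).any():
            raise ValueError("need 0 <= meth <= total for every CpG")

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)
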
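"""Sliding-window selective-sweep scan: outlier selection, region calling,
gene assignment and fine mapping.

Outliers are chosen by rank ("the top fraction of windows"), independently
for windowed Fst and for |log2 pi-ratio|; the reported threshold per
criterion is the smallest selected value, which is how empirical cutoffs such
as an Fst of 0.476 at the 1% tail arise as outputs of a scan rather than as
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneModel, GenotypeTable, ScanConfig

FST = "FST"
PI_RATIO = "PI_RATIO"


@dataclass
class ScanThresholds:
    fst_threshold: float
    log2_ratio_threshold: float
    n_selected_fst: int
    n_selected_ratio: int

    def to_dict(self) -> dict:
        return {
            "fst_threshold": self.fst_threshold,
            "log2_ratio_threshold": self.log2_ratio_threshold,
            "n_selected_fst": self.n_selected_fst,
            "n_selected_ratio": self.n_selected_ratio,
        }


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    criteria: set
    peak_fst: float
    peak_abs_log2_ratio: float
    genes: list[str] = field(default_factory=list)


def make_windows(chrom_length: int, window_bp: int, step_bp: int
                 ) -> list[tuple[int, int]]:
    """Sliding windows [k*step, k*step + window) clipped at the chromosome
    end; every start strictly inside the chromosome yields a window, so the
    tail is covered by (possibly partial) windows."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    out = []
    start = 0
    while start < chrom_length:
        out.append((start, min(start + window_bp, chrom_length)))
        start += step_bp
    return out


def _top_k_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest finite values (stable order, ties by
    earlier index win)."""
    mask = np.zeros(len(values), dtype=bool)
    finite = np.flatnonzero(np.isfinite(values))
    order = finite[np.argsort(-values[finite], kind="stable")]
    mask[order[:k]] = True
    return mask


def select_outlier_windows(windows: pd.DataFrame, config: ScanConfig,
                           min_windows: int = 100
                           ) -> tuple[ScanThresholds, pd.DataFrame]:
    """Pick outlier windows by rank or by fixed thresholds.

    Rank mode selects the top ceil(top_fraction * N) windows per criterion,
    with N the windows carrying a finite value for that criterion; fixed
    thresholds (strict >) override rank selection when set. Returns the
    thresholds actually realised and the windows table with boolean
    ``sel_fst`` / ``sel_ratio`` columns plus a ``selected`` union column.
    """
    df = windows.copy()
    fst = df["fst_win"].to_numpy(dtype=float)
    ratio = df["log2_pi_ratio"].to_numpy(dtype=float)
    score_ratio = -ratio if config.one_sided_alk_depleted else np.abs(ratio)

    if config.fst_min is None or config.abs_log2_ratio_min is None:
        n_ok = min(np.isfinite(fst).sum(), np.isfinite(score_ratio).sum())
        if n_ok < min_windows:
            raise ValueError(
                f"only {n_ok} usable windows; percentile selection needs at least "
                f"{min_windows} — set fixed thresholds (fst_min, abs_log2_ratio_min)")

    if config.fst_min is not None:
        sel_fst = np.isfinite(fst) & (fst > config.fst_min)
    else:
        k = math.ceil(config.top_fraction * np.isfinite(fst).sum())
        sel_fst = _top_k_mask(fst, k)
    if config.abs_log2_ratio_min is not None:
        sel_ratio = np.isfinite(score_ratio) & (score_ratio > config.abs_log2_ratio_min)
    else:
        k = math.ceil(config.top_fraction * np.isfinite(score_ratio).sum())
        sel_ratio = _top_k_mask(score_ratio, k)

    thresholds = ScanThresholds(
        fst_threshold=float(fst[sel_fst].min()) if sel_fst.any() else np.nan,
        log2_ratio_threshold=(float(score_ratio[sel_ratio].min())
                              if sel_ratio.any() else np.nan),
        n_selected_fst=int(sel_fst.sum()),
        n_selected_ratio=int(sel_ratio.sum()),
    )
    df["sel_fst"] = sel_fst
    df["sel_ratio"] = sel_ratio
    df["selected"] = sel_fst | sel_ratio
    return thresholds, df


def call_candidate_regions(selected: pd.DataFrame, merge_gap_bp: int = 0
                           ) -> list[CandidateRegion]:
    """Merge overlapping or book-ended selected windows into regions.

    ``selected`` is the window table restricted to selected rows (or carrying
    a ``selected`` column). Criteria are unioned and peaks maximised over the
    member windows. Idempotent: merging already-merged regions returns them.
    """
    if "selected" in selected.columns:
        selected = selected[selected["selected"]]
    if selected.empty:
        return []
    selected = selected.sort_values(["chrom", "start"], kind="stable")
    regions: list[CandidateRegion] = []
    cur: CandidateRegion | None = None
    for row in selected.itertuples(index=False):
        crit = set()
        if getattr(row, "sel_fst", True):
            crit.add(FST)
        if getattr(row, "sel_ratio", True):
            crit.add(PI_RATIO)
        fst = float(row.fst_win) if np.isfinite(row.fst_win) else -np.inf
        ratio = (abs(float(row.log2_pi_ratio))
                 if np.isfinite(row.log2_pi_ratio) else -np.inf)
        if cur is not None and row.chrom == cur.chrom and row.start <= cur.end + merge_gap_bp:
            cur.end = max(cur.end, int(row.end))
            cur.criteria |= crit
            cur.peak_fst = max(cur.peak_fst, fst)
            cur.peak_abs_log2_ratio = max(cur.peak_abs_log2_ratio, ratio)
        else:
            cur = CandidateRegion(str(row.chrom), int(row.start), int(row.end),
                                  crit, fst, ratio)
            regions.append(cur)
    return regions


def assign_genes(regions: list[CandidateRegion], genes: list[GeneModel]
                 ) -> list[CandidateRegion]:
    """Attach every gene whose span overlaps a region by >= 1 bp (half-open)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for region in regions:
        region.genes = sorted(
            g.gene_id for g in by_chrom.get(region.chrom, [])
            if g.gene_span[0] < region.end and g.gene_span[1] > region.start
        )
    return regions


def fine_map(region: CandidateRegion, table: GenotypeTable,
             chrom_length: int, config: ScanConfig | None = None) -> pd.DataFrame:
    """Recompute Fst, pi-ratio and Tajima's D on a fine non-overlapping grid
    over the region padded by one fine window on each side."""
    from .popstats import window_stats

    cfg = config or ScanConfig()
    w = cfg.fine_window_bp
    start = max(0, region.start - w)
    end = min(chrom_length, region.end + w)
    wins = [(s, min(s + w, end)) for s in range(start, end, w)]
    fine_cfg = ScanConfig(window_bp=w, step_bp=w,
                          fine_window_bp=w, top_fraction=cfg.top_fraction)
    return window_stats(table, {region.chrom: chrom_length}, fine_cfg,
                        windows_by_chrom={region.chrom: wins})


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """BED-compatible region table (0-based half-open)."""
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "criteria": ",".join(sorted(r.criteria)),
        "peak_fst": r.peak_fst,
        "peak_abs_log2_ratio": r.peak_abs_log2_ratio,
        "genes": ",".join(r.genes),
    } for r in regions])
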
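"""Per-site and per-window population-genetic estimators.

Site differentiation uses the Weir & Cockerham (1984) two-population
variance-components estimator theta-hat = a / (a + b + c), computed from
sample sizes, allele frequencies and *observed* heterozygote counts; windowed
Fst is the ratio of sums sum(a) / sum(a + b + c) over sites (the weighted
estimator, as in vcftools --fst-window). Nucleotide diversity per site is the
unbiased pairwise estimator 2*p*(1-p)*n/(n-1) with n the called chromosomes,
and per-window pi divides the sum by the full window span in bp. Tajima's D
follows Tajima (1989) with the standard a1..e2 constants.

All estimators propagate NaN for undefined cases (monomorphic across both
populations, too few called samples); NaN rows are excluded from percentile
computations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ALK, FW, GenotypeTable, ScanConfig


# ---------------------------------------------------------------------------
# per-site building blocks


@dataclass
class PopCounts:
    """Per-site allelic summaries for one population (vectors over sites)."""

    alt: np.ndarray      # alt-allele count
    called: np.ndarray   # called chromosomes (2 * called diploids)
    het: np.ndarray      # observed heterozygote (dosage == 1) individuals

    @property
    def n_diploid(self) -> np.ndarray:
        return self.called // 2

    @property
    def p(self) -> np.ndarray:
        """Alt-allele frequency; NaN where no allele was called."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.called > 0, self.alt / self.called, np.nan)


def pop_counts(table: GenotypeTable, label: str) -> PopCounts:
    d = table.pop_dosage(label)
    called_mask = d >= 0
    return PopCounts(
        alt=np.where(called_mask, d, 0).sum(axis=1),
        called=2 * called_mask.sum(axis=1),
        het=(d == 1).sum(axis=1),
    )


def site_frequencies(table: GenotypeTable) -> pd.DataFrame:
    """Per-site (p_alk, p_fw, n_alk, n_fw); n in called chromosomes."""
    a, f = pop_counts(table, ALK), pop_counts(table, FW)
    return pd.DataFrame({
        "chrom": table.chrom, "pos": table.pos,
        "p_alk": a.p, "p_fw": f.p,
        "n_alk": a.called, "n_fw": f.called,
    })


def wc_fst_components(alk: PopCounts, fw: PopCounts) -> tuple[np.ndarray, ...]:
    """Weir & Cockerham (1984) variance components (a, b, c) per site, r = 2.

    Sites with fewer than 2 called diploids in either population get NaN
    components. h_bar uses observed heterozygote fractions, so the estimator
    is robust to within-population inbreeding.
    """
    n1 = alk.n_diploid.astype(float)
    n2 = fw.n_diploid.astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = alk.p, fw.p
        h1 = alk.het / n1
        h2 = fw.het / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = ~ok
    for comp in (a, b, c):
        comp[bad] = np.nan
    return a, b, c


def wc_fst_site(alk: PopCounts, fw: PopCounts) -> np.ndarray:
    """Per-site theta-hat = a/(a+b+c); NaN when the denominator is zero."""
    a, b, c = wc_fst_components(alk, fw)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return fst


def wc_fst_ratio_of_sums(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Windowed Fst: sum(a) / sum(a+b+c) over non-NaN sites; NaN if none."""
    denom = a + b + c
    ok = np.isfinite(denom)
    if not ok.any():
        return np.nan
    tot = denom[ok].sum()
    return float(a[ok].sum() / tot) if tot != 0 else np.nan


def site_pi(counts: PopCounts) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2p(1-p) n/(n-1); 0 from n<2 sites."""
    n = counts.called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2 * counts.p * (1 - counts.p) * n / (n - 1)
    return np.where(n >= 2, pi, 0.0)


def window_pi(counts: PopCounts, site_index: np.ndarray, span_bp: int) -> float:
    """Per-bp pi over a window: sum of per-site pi divided by the window span."""
    if span_bp <= 0:
        raise ValueError("window span must be positive")
    return float(site_pi(counts)[site_index].sum() / span_bp)


def pi_ratio_log2(pi_alk: float, pi_fw: float, pseudo_floor: float) -> tuple[float, bool]:
    """log2(pi_ALK / pi_FW); zero diversities are floored and flagged."""
    flagged = False
    if pi_alk <= 0 or pi_fw <= 0:
        pi_alk = max(pi_alk, pseudo_floor)
        pi_fw = max(pi_fw, pseudo_floor)
        flagged = True
    return float(np.log2(pi_alk / pi_fw)), flagged


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalisation constants for sample size n chromosomes."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(counts: PopCounts, site_index: np.ndarray,
              n_tolerance: float = 0.2) -> float:
    """Tajima's D for one population over the sites in a window.

    With missing data the sample size varies by site; the modal called-
    chromosome count over the window is used for the constants, and sites
    whose n deviates from the mode by more than ``n_tolerance`` (relative) are
    excluded. NaN when no segregating sites remain or modal n < 4.
    """
    called = counts.called[site_index]
    usable = called >= 2
    if not usable.any():
        return np.nan
    vals, freq = np.unique(called[usable], return_counts=True)
    n_modal = int(vals[np.argmax(freq)])
    if n_modal < 4:
        return np.nan
    keep = usable & (np.abs(called - n_modal) <= n_tolerance * n_modal)
    idx = site_index[keep]
    p = counts.p[idx]
    seg = (counts.alt[idx] > 0) & (counts.alt[idx] < counts.called[idx])
    s = int(seg.sum())
    if s == 0:
        return np.nan
    pi_hat = float(site_pi(counts)[idx].sum())
    k = tajima_constants(n_modal)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return np.nan
    return float((pi_hat - s / k["a1"]) / np.sqrt(var))


def site_stats(table: GenotypeTable) -> pd.DataFrame:
    """Per-variant SiteStats: Fst, expected heterozygosities, delta-H, MAFs.

    delta_h = h_FW - h_ALK, so diversity loss in the alkaline population shows
    as positive delta-H. Heterozygosity is the expected 2p(1-p).
    """
    a, f = pop_counts(table, ALK), pop_counts(table, FW)
    fst = wc_fst_site(a, f)
    h_alk = 2 * a.p * (1 - a.p)
    h_fw = 2 * f.p * (1 - f.p)
    return pd.DataFrame({
        "chrom": table.chrom, "pos": table.pos,
        "ref": table.ref, "alt": table.alt, "is_snp": table.is_snp,
        "fst": fst,
        "h_alk": h_alk, "h_fw": h_fw, "delta_h": h_fw - h_alk,
        "maf_alk": np.minimum(a.p, 1 - a.p),
        "maf_fw": np.minimum(f.p, 1 - f.p),
    })


# ---------------------------------------------------------------------------
# windowed scan


def window_stats(table: GenotypeTable, chrom_lengths: dict[str, int],
                 config: ScanConfig | None = None,
                 windows_by_chrom: dict[str, list[tuple[int, int]]] | None = None,
                 ) -> pd.DataFrame:
    """Windowed pi (both populations), log2 pi-ratio, Fst and Tajima's D.

    Windows default to the sliding grid from ``make_windows``; an explicit
    per-chromosome window list overrides it (used by fine mapping). The
    pi-ratio pseudo-floor is the smallest nonzero per-bp pi observed over all
    windows and both populations.
    """
    from .scan import make_windows

    cfg = config or ScanConfig()
    alk, fw = pop_counts(table, ALK), pop_counts(table, FW)
    comp_a, comp_b, comp_c = wc_fst_components(alk, fw)
    pi_alk_site = site_pi(alk)
    pi_fw_site = site_pi(fw)

    rows = []
    for chrom, length in chrom_lengths.items():
        wins = (windows_by_chrom or {}).get(chrom) if windows_by_chrom else None
        if wins is None:
            if windows_by_chrom is not None:
                continue
            wins = make_windows(length, cfg.window_bp, cfg.step_bp)
        on_chrom = np.flatnonzero(table.chrom == chrom)
        pos = table.pos[on_chrom]
        for start, end in wins:
            lo, hi = np.searchsorted(pos, [start, end])
            idx = on_chrom[lo:hi]
            span = end - start
            denom = comp_a[idx] + comp_b[idx] + comp_c[idx]
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_sites": len(idx),
                "pi_alk": pi_alk_site[idx].sum() / span,
                "pi_fw": pi_fw_site[idx].sum() / span,
                "fst_win": wc_fst_ratio_of_sums(comp_a[idx], comp_b[idx], comp_c[idx]),
                "tajd_alk": tajimas_d(alk, idx),
                "tajd_fw": tajimas_d(fw, idx),
                "partial": span < cfg.window_bp,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    nonzero = np.concatenate([df["pi_alk"].values, df["pi_fw"].values])
    nonzero = nonzero[nonzero > 0]
    floor = float(nonzero.min()) if len(nonzero) else 1e-9
    ratios, flags = [], []
    for pa, pf in zip(df["pi_alk"], df["pi_fw"]):
        r, fl = pi_ratio_log2(pa, pf, floor)
        ratios.append(r)
        flags.append(fl)
    df["log2_pi_ratio"] = ratios
    df["ratio_floored"] = flags
    return df[["chrom", "start", "end", "n_sites", "pi_alk", "pi_fw",
               "log2_pi_ratio", "ratio_floored", "fst_win",
               "tajd_alk", "tajd_fw", "partial"]]


def per_chromosome_pi(windows: pd.DataFrame) -> pd.DataFrame:
    """Mean per-window pi per chromosome for each population."""
    return windows.groupby("chrom", as_index=False)[["pi_alk", "pi_fw"]].mean()


def compare_diversity(pi_alk: np.ndarray, pi_fw: np.ndarray) -> dict:
    """Paired two-sided t-test on per-chromosome mean diversities.

    Returns {'t', 'p', 'degenerate'}. Identical vectors give (0, 1); a
    nonzero constant difference has zero variance and is flagged degenerate
    with p = NaN.
    """
    x = np.asarray(pi_alk, dtype=float)
    y = np.asarray(pi_fw, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return {"t": 0.0, "p": 1.0, "degenerate": True}
        return {"t": np.nan, "p": np.nan, "degenerate": True}
    t, p = sps.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "degenerate": False}
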
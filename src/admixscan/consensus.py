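"""Consensus candidate-region caller combining all evidence streams.

A window is a *candidate* when flagged by at least two EHH-based tests; it
is *relevant* when, in addition, the supporting cross-population tests have
positive sign (longer haplotypes in the target, i.e. selection there) and
the window — or an immediately adjacent window — shows an excess of one of
the three ancestries. Top-percentile Fst, reduced diversity, the
chromosome-maximum CLR and ROH-island overlap are attached as corroborative
flags; they never gate relevance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import SOURCES, WindowGrid


def _overlaps(chrom, start, end, table: pd.DataFrame) -> bool:
    if table is None or len(table) == 0:
        return False
    sub = table[table["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def call_consensus(ehh_calls: dict[str, pd.DataFrame],
                   grid: WindowGrid,
                   ancestry_windows: pd.DataFrame | None = None,
                   fst_tops: dict[str, pd.DataFrame] | None = None,
                   pi_windows: pd.DataFrame | None = None,
                   clr_results: pd.DataFrame | None = None,
                   roh_islands: pd.DataFrame | None = None,
                   within_population_tests: tuple[str, ...] = ("iHS",),
                   pi_pct: float = 10.0) -> pd.DataFrame:
    """Combine evidence streams into candidate regions on the EHH grid.

    Parameters mirror the upstream stages: ``ehh_calls`` maps test name to
    the per-window outlier classification (all on ``grid``);
    ``ancestry_windows`` comes from :func:`ancestry_excess_windows` (any
    grid; matched by bp overlap, with the ±1-window vicinity rule);
    ``fst_tops`` maps comparison name to its top-percentile window set;
    ``pi_windows`` are 50-kb diversity windows (the reduction flag marks
    candidates overlapping a window below their chromosome's ``pi_pct``-th
    percentile); ``clr_results`` and ``roh_islands`` as produced upstream.
    Missing streams simply leave their flags False.
    """
    for name, df in ehh_calls.items():
        if not df[["chrom", "start", "end"]].equals(
                grid.windows[["chrom", "start", "end"]]):
            raise ValueError(f"EHH window calls for {name!r} are not on the "
                             "consensus grid")

    # per-chromosome low-pi thresholds on the diversity grid
    pi_low = None
    if pi_windows is not None and len(pi_windows):
        pw = pi_windows[pi_windows["n_snps"] > 0]
        thr = pw.groupby("chrom")["pi"].quantile(pi_pct / 100.0)
        pi_low = pw[pw["pi"] <= pw["chrom"].map(thr)]

    clr_max = None
    if clr_results is not None and len(clr_results):
        from .clr import chromosome_maxima
        clr_max = chromosome_maxima(clr_results)

    excess_cols = [f"excess_{a}" for a in SOURCES]
    rows = []
    windows = grid.windows
    for i, (chrom, start, end) in enumerate(windows.itertuples(index=False)):
        supporting = [name for name, df in ehh_calls.items()
                      if bool(df["flagged"].iloc[i])]
        if len(supporting) < 2:
            continue
        cross = [n for n in supporting if n not in within_population_tests]
        signs = [float(ehh_calls[n]["sign"].iloc[i]) for n in cross]
        sign_positive = bool(len(signs) and np.median(signs) > 0)

        excess_ancestries = []
        if ancestry_windows is not None and len(ancestry_windows):
            aw = ancestry_windows
            near = aw[(aw["chrom"] == chrom)
                      & (aw["start"] < end + grid.width)
                      & (aw["end"] > start - grid.width)]
            for a, col in zip(SOURCES, excess_cols):
                if col in near.columns and bool(near[col].any()):
                    excess_ancestries.append(a)
        has_excess = bool(excess_ancestries)

        fst_hits = [cmp for cmp, tops in (fst_tops or {}).items()
                    if _overlaps(chrom, start, end, tops)]
        pi_reduced = _overlaps(chrom, start, end, pi_low) if pi_low is not None else False
        is_clr_max = _overlaps(chrom, start, end, clr_max) if clr_max is not None else False
        roh_hit = _overlaps(chrom, start, end, roh_islands) if roh_islands is not None else False

        rows.append({
            "chrom": chrom, "start": start, "end": end,
            "n_tests": len(supporting), "tests": ",".join(sorted(supporting)),
            "sign_positive": sign_positive,
            "ancestry_excess": has_excess,
            "excess_ancestry": ",".join(excess_ancestries),
            "top_fst": ",".join(sorted(fst_hits)),
            "pi_reduction": bool(pi_reduced),
            "clr_chrom_max": bool(is_clr_max),
            "roh_island": bool(roh_hit),
            "relevant": bool(len(supporting) >= 2 and sign_positive
                             and has_excess),
        })
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_tests", "tests", "sign_positive",
        "ancestry_excess", "excess_ancestry", "top_fst", "pi_reduction",
        "clr_chrom_max", "roh_island", "relevant"])
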
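"""Relative fitness estimation from barcode counts.

Malthusian fitness of focal lineage *i* relative to the reference over one
competition assay (G = 20 generations across two 48-hour growth cycles):

    m_i = ( ln(C_i,48h / C_i,0h) - ln(R_48h / R_0h) ) / G

Wrightian fitness is w = exp(m), and the fitness change of a lineage over the
50-day evolution is

    dw = ( mean w_Day-50 - mean w_Day-0 ) x 100   [percentage points]

Missing counts (the low-count filter) propagate: any computation touching a
missing count yields a missing fitness value, never zero.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .barcode_io import BarcodeLibrary, SampleSheet

logger = logging.getLogger("barfit")

FITNESS_COLUMNS = [
    "pool_id",
    "chemical",
    "stress_fraction",
    "day",
    "replicate",
    "barcode",
    "m",
    "w",
]


def malthusian_fitness(c0, c48, r0, r48, generations: float = 20.0):
    """Per-generation log fitness of the focal barcode relative to the reference.

    Vectorized; any missing (NaN) or non-positive count yields NaN.  Zero
    counts cannot occur after the low-count filter (threshold >= 20) but are
    guarded against and logged when they do.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    c0 = np.asarray(c0, dtype=float)
    c48 = np.asarray(c48, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    r48 = np.asarray(r48, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = (c0 > 0) & (c48 > 0) & (r0 > 0) & (r48 > 0)
        m = np.where(
            valid,
            (np.log(c48 / c0) - np.log(r48 / r0)) / generations,
            np.nan,
        )
    n_zero = int(np.sum(~valid & ~(np.isnan(c0) | np.isnan(c48) | np.isnan(r0) | np.isnan(r48))))
    if n_zero:
        logger.warning("%d fitness values dropped due to zero counts", n_zero)
    if m.ndim == 0:
        return float(m)
    return m


def wrightian(m):
    """Wrightian (multiplicative) fitness w = exp(m); NaN propagates."""
    out = np.exp(np.asarray(m, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def assemble_fitness_table(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    library: BarcodeLibrary,
    generations: float = 20.0,
    pairing: Literal["mean", "per_replicate"] = "mean",
) -> pd.DataFrame:
    """Join 0-hour and 48-hour samples into one (m, w) per lineage x assay.

    Within each (pool, chemical, stress fraction, day) group, the default
    pairing sets every 48-hour replicate against the mean of the quintuplicate
    0-hour initial measures; ``pairing="per_replicate"`` instead matches
    replicate numbers one-to-one.  A 48-hour sample whose reference count is
    missing yields missing fitness for that whole sample (logged).

    ``counts`` should be the low-count-filtered table.
    """
    if pairing not in ("mean", "per_replicate"):
        raise ValueError(f"unknown pairing {pairing!r}")
    ref = library.reference_id
    meta = sheet.df[~sheet.df["sentinel"].astype(bool)]
    merged = counts.merge(
        meta[
            [
                "sample_id",
                "pool_id",
                "chemical",
                "stress_fraction",
                "day",
                "timepoint_h",
                "replicate",
            ]
        ],
        on="sample_id",
        how="inner",
    )

    records: list[tuple] = []
    group_cols = ["pool_id", "chemical", "stress_fraction", "day"]
    for key, grp in merged.groupby(group_cols, sort=False):
        t0 = grp[grp["timepoint_h"] == 0]
        t48 = grp[grp["timepoint_h"] == 48]
        if t0.empty or t48.empty:
            logger.warning("assay group %s lacks a timepoint; skipped", key)
            continue
        # mean of initial measures per barcode (NaN-aware; all-missing -> NaN)
        c0_mean = t0.groupby("barcode")["reads"].mean()
        if pairing == "per_replicate":
            c0_by_rep = {
                rep: sub.set_index("barcode")["reads"]
                for rep, sub in t0.groupby("replicate")
            }
            t0_reps = sorted(c0_by_rep)
        for rep, sub48 in t48.groupby("replicate"):
            c48 = sub48.set_index("barcode")["reads"]
            if pairing == "per_replicate":
                c0 = c0_by_rep[t0_reps[(int(rep) - 1) % len(t0_reps)]]
            else:
                c0 = c0_mean
            barcodes = [b for b in c48.index if b != ref]
            r0 = c0.get(ref, np.nan)
            r48 = c48.get(ref, np.nan)
            if not np.isfinite(r48) or not np.isfinite(r0):
                logger.warning(
                    "reference barcode missing in assay group %s replicate %s; "
                    "all fitness values for this sample are missing",
                    key,
                    rep,
                )
            m = malthusian_fitness(
                c0.reindex(barcodes).to_numpy(),
                c48.reindex(barcodes).to_numpy(),
                r0,
                r48,
                generations=generations,
            )
            w = wrightian(m)
            pool_id, chem, frac, day = key
            for b, mi, wi in zip(barcodes, np.atleast_1d(m), np.atleast_1d(w)):
                records.append((pool_id, chem, frac, day, rep, b, mi, wi))

    return pd.DataFrame(records, columns=FITNESS_COLUMNS)


def delta_fitness(
    fitness: pd.DataFrame,
    per_replicate: bool = False,
    scale: float = 100.0,
) -> pd.DataFrame:
    """Fitness change per lineage x assay environment, in percentage points.

    Day-0 fitness is measured on the shared template pool, so it is keyed by
    (barcode, chemical, stress fraction) and joined to every Day-50 lineage
    (= pool:barcode) carrying that barcode.  Default: mean Day-50 w minus mean
    Day-0 w, over non-missing replicates (mean-then-subtract).  With
    ``per_replicate=True`` one row per Day-50 replicate is returned (each
    minus the Day-0 mean), the form consumed by the mixed-effects model.
    Lineages with all replicates missing on either day get a missing dw.
    """
    env_cols = ["barcode", "chemical", "stress_fraction"]
    day0 = fitness[fitness["day"] == 0]
    day50 = fitness[fitness["day"] == 50]
    if day0.empty or day50.empty:
        raise ValueError("need both Day-0 and Day-50 fitness records")

    w0 = (
        day0.groupby(env_cols)["w"]
        .agg(w0_mean="mean", n0=lambda s: int(s.notna().sum()))
        .reset_index()
    )

    if per_replicate:
        merged = day50.merge(w0, on=env_cols, how="left")
        merged["dw"] = (merged["w"] - merged["w0_mean"]) * scale
        merged.loc[merged["n0"].fillna(0) == 0, "dw"] = np.nan
        merged["lineage"] = merged["pool_id"] + ":" + merged["barcode"]
        return merged[
            ["lineage", "pool_id", "barcode", "chemical", "stress_fraction", "replicate", "dw", "n0"]
        ].reset_index(drop=True)

    w50 = (
        day50.groupby(["pool_id"] + env_cols)["w"]
        .agg(w50_mean="mean", n50=lambda s: int(s.notna().sum()))
        .reset_index()
    )
    merged = w50.merge(w0, on=env_cols, how="left")
    merged["dw"] = (merged["w50_mean"] - merged["w0_mean"]) * scale
    bad = (merged["n50"] == 0) | (merged["n0"].fillna(0) == 0)
    merged.loc[bad, "dw"] = np.nan
    merged["lineage"] = merged["pool_id"] + ":" + merged["barcode"]
    return merged[
        ["lineage", "pool_id", "barcode", "chemical", "stress_fraction", "dw", "n0", "n50"]
    ].reset_index(drop=True)
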
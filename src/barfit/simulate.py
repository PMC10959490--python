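"""Synthetic Bar-seq experiment generator.

Produces ground-truth lineage fitness effects and pooled-competition read
counts (optionally FASTQ) with the statistical structure the analysis assumes:

* 50-day evolution is represented by its Day-0 / Day-50 endpoints only — the
  analysis never looks at intermediate days.
* One ancestral plate layout (treatment x population x barcode) is copied onto
  ``plates_per_chemical`` microplates per chemical, so barcodes are unique
  within but not between plates.  Lineage identity is (plate, barcode).
* Competition assays: one Day-0 template pool plus one Day-50 pool per plate,
  each spiked with the reference strain at ~70%, grown for G = 20 generations
  under the deterministic replicator update, then read-sampled multinomially
  at a given depth.  Initial mixtures are measured in quintuplicate and final
  cultures in quadruplicate, as separate sequencing samples.
* Barcode cross-contamination reassigns a binomial fraction of a sample's
  reads to library barcodes not expected in that sample.

All randomness flows from one integer seed through spawned numpy generators.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .barcode_io import COUNT_COLUMNS, BarcodeLibrary, SampleSheet, SHEET_COLUMNS
from .design import ExperimentalDesign
from .layout import DEFAULT_LAYOUT, ReadLayout

logger = logging.getLogger("barfit")

TRADEOFF_MODES = ("antagonistic_pleiotropy", "conditional_neutrality", "complementary")

REFERENCE_ID = "d1H10"


class SimulationError(ValueError):
    pass


# ------------------------------------------------------------------ library


def make_library(n_barcodes: int, seed: int, reference_id: str = REFERENCE_ID) -> BarcodeLibrary:
    """Random unique 20-mers for ``n_barcodes`` lineage barcodes plus the reference."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0C0DE]))
    seqs: dict[str, str] = {}
    seen: set[str] = set()
    ids = [reference_id] + [f"b{i:04d}" for i in range(n_barcodes)]
    bases = np.array(list("ACGT"))
    for bc_id in ids:
        while True:
            seq = "".join(rng.choice(bases, size=20))
            if seq not in seen:
                seen.add(seq)
                seqs[bc_id] = seq
                break
    return BarcodeLibrary(sequences=seqs, reference_id=reference_id)


def ancestral_layout(design: ExperimentalDesign) -> pd.DataFrame:
    """The shared plate layout: barcode -> (treatment name, population slot).

    The same physical layout seeds every microplate, so this table is
    plate-independent.
    """
    rows = []
    i = 0
    for name in design.treatment_names:
        for pop in range(design.populations_per_plate):
            for _ in range(design.barcodes_per_population):
                rows.append((f"b{i:04d}", name, pop))
                i += 1
    return pd.DataFrame(rows, columns=["barcode", "treatment", "population_slot"])


# ------------------------------------------------------------------ true effects


@dataclass
class TrueFitnessModel:
    """Ground-truth Wrightian fitness per lineage per assay environment.

    ``effects`` has one row per (plate, barcode, assay stress fraction) with
    the lineage's true relative fitness at Day 0 (always 1: strains start
    equivalent to the reference) and at Day 50.  ``dw_true`` is the true
    fitness change in percentage points.
    """

    design: ExperimentalDesign
    effects: pd.DataFrame
    mode: str
    params: dict
    seed: int

    def lineage_map(self) -> pd.DataFrame:
        cols = ["lineage", "plate", "barcode", "chemical", "treatment", "population"]
        return self.effects[cols].drop_duplicates().reset_index(drop=True)

    def w50(self, plate: str, stress_fraction: float) -> pd.Series:
        sub = self.effects[
            (self.effects["plate"] == plate)
            & (self.effects["stress_fraction"] == stress_fraction)
        ]
        return sub.set_index("barcode")["w50"]


def _mean_effect(treatment, stress_fraction: float, mode: str,
                 home_gain: float, away_loss: float) -> float:
    """Mean Day-50 fitness effect for a lineage history at one assay environment.

    Antagonistic pleiotropy: gains at environments in the evolution schedule,
    losses elsewhere, weighted by time share.  Conditional neutrality: gains at
    home, nothing elsewhere.  Complementary: a single across-environment gain
    whose size grows with the stress history (0.5 + mean schedule fraction),
    so stress-adapted lineages outperform everywhere.
    """
    tau = treatment.time_fraction(stress_fraction)
    if mode == "antagonistic_pleiotropy":
        return home_gain * tau - away_loss * (1.0 - tau)
    if mode == "conditional_neutrality":
        return home_gain * tau
    if mode == "complementary":
        return home_gain * (0.5 + treatment.mean_fraction)
    raise SimulationError(f"unknown trade-off mode {mode!r}; expected one of {TRADEOFF_MODES}")


def draw_true_effects(
    design: ExperimentalDesign,
    mode: str = "antagonistic_pleiotropy",
    home_gain: float = 0.05,
    away_loss: float = 0.03,
    cross_env_rho: float = 0.0,
    effect_sd: float = 0.02,
    within_population_rho: float = 0.0,
    seed: int = 0,
) -> TrueFitnessModel:
    """Draw Day-50 true fitness for every lineage in every assay environment.

    Lineage deviations around the mode's mean surface are multivariate normal
    across assay environments with exchangeable correlation ``cross_env_rho``
    and marginal s.d. ``effect_sd``.  ``within_population_rho`` optionally
    correlates the two barcodes that co-inhabit a population (default
    independent).  Day-0 fitness is 1 everywhere.
    """
    if mode not in TRADEOFF_MODES:
        raise SimulationError(f"unknown trade-off mode {mode!r}; expected one of {TRADEOFF_MODES}")
    if not -1.0 <= cross_env_rho <= 1.0:
        raise SimulationError("cross_env_rho must lie in [-1, 1]")
    if effect_sd < 0:
        raise SimulationError("effect_sd must be >= 0")
    if not 0.0 <= within_population_rho <= 1.0:
        raise SimulationError("within_population_rho must lie in [0, 1]")

    fractions = np.asarray(design.assay_fractions, dtype=float)
    k = len(fractions)
    cov = np.full((k, k), cross_env_rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    if np.linalg.eigvalsh(cov)[0] < -1e-9:
        raise SimulationError(
            f"cross_env_rho={cross_env_rho} is infeasible for {k} environments"
        )
    cov = cov * effect_sd**2

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEFFEC7]))
    layout = ancestral_layout(design)

    rows = []
    for chem in design.chemicals:
        for plate_idx in range(design.plates_per_chemical):
            plate = f"{chem}{plate_idx + 1}"
            for (tname, pop_slot), group in layout.groupby(
                ["treatment", "population_slot"], sort=False
            ):
                treatment = design.treatment(chem, tname)
                population = f"{plate}:{tname}:p{pop_slot}"
                pop_noise = rng.multivariate_normal(np.zeros(k), cov, method="eigh")
                for barcode in group["barcode"]:
                    own = rng.multivariate_normal(np.zeros(k), cov, method="eigh")
                    noise = (
                        np.sqrt(within_population_rho) * pop_noise
                        + np.sqrt(1.0 - within_population_rho) * own
                    )
                    mu = np.array(
                        [
                            _mean_effect(treatment, f, mode, home_gain, away_loss)
                            for f in fractions
                        ]
                    )
                    w50 = np.maximum(1.0 + mu + noise, 1e-2)
                    for f, w in zip(fractions, w50):
                        rows.append(
                            (
                                f"{plate}:{barcode}",
                                plate,
                                barcode,
                                chem,
                                tname,
                                population,
                                f,
                                1.0,
                                float(w),
                                100.0 * (float(w) - 1.0),
                            )
                        )

    effects = pd.DataFrame(
        rows,
        columns=[
            "lineage",
            "plate",
            "barcode",
            "chemical",
            "treatment",
            "population",
            "stress_fraction",
            "w0",
            "w50",
            "dw_true",
        ],
    )
    params = {
        "home_gain": home_gain,
        "away_loss": away_loss,
        "cross_env_rho": cross_env_rho,
        "effect_sd": effect_sd,
        "within_population_rho": within_population_rho,
    }
    return TrueFitnessModel(design=design, effects=effects, mode=mode, params=params, seed=int(seed))


# ------------------------------------------------------------------ assay draws


@dataclass
class AssayCounts:
    """Read counts for one sequenced sample (one timepoint of one assay well)."""

    sample_id: str
    barcodes: list[str]
    reads: np.ndarray
    depth: int
    contamination_rate: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "barcode": self.barcodes,
                "reads": self.reads.astype(int),
            }
        )


def replicator_expectation(f0: np.ndarray, w: np.ndarray, generations: float) -> np.ndarray:
    """Expected pool frequencies after ``generations`` of relative growth.

    f48_i = f0_i * w_i**G / sum_j f0_j * w_j**G  (the reference has w = 1).
    """
    f0 = np.asarray(f0, dtype=float)
    w = np.asarray(w, dtype=float)
    growth = f0 * np.power(w, generations)
    total = growth.sum()
    if total <= 0:
        raise SimulationError("degenerate pool: total expected growth is zero")
    return growth / total


def simulate_assay(
    w: np.ndarray,
    f0: np.ndarray,
    generations: float = 20.0,
    depth: int = 100_000,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw 0-hour and 48-hour read counts for one competition assay.

    ``w`` holds true relative fitness per pool member (reference = 1), ``f0``
    the starting frequencies (must sum to 1).  With ``exact=True`` counts are
    rounded expectations at the given depth (use a large depth such as 1e9 for
    an effectively noise-free assay); otherwise both timepoints are multinomial
    draws.
    """
    f0 = np.asarray(f0, dtype=float)
    if f0.size == 0:
        raise SimulationError("empty pool")
    if depth <= 0:
        raise SimulationError("sequencing depth must be positive")
    if generations <= 0:
        raise SimulationError("generations must be positive")
    if abs(f0.sum() - 1.0) > 1e-9:
        raise SimulationError("pool frequencies must sum to 1")
    f48 = replicator_expectation(f0, w, generations)
    if exact:
        c0 = np.rint(f0 * depth).astype(np.int64)
        c48 = np.rint(f48 * depth).astype(np.int64)
        return c0, c48
    if rng is None:
        rng = np.random.default_rng()
    c0 = rng.multinomial(int(depth), f0)
    c48 = rng.multinomial(int(depth), f48)
    return c0, c48


def inject_contamination(
    counts: AssayCounts,
    rate: float,
    library: BarcodeLibrary,
    expected: set[str],
    rng: np.random.Generator,
) -> AssayCounts:
    """Reassign a binomial fraction ~``rate`` of reads to unexpected barcodes.

    Contaminating reads land uniformly on library barcodes outside
    ``expected`` and excluding the reference.  With no eligible target
    barcodes (every library barcode expected) counts are returned unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise SimulationError("contamination rate must lie in [0, 1)")
    if rate == 0.0:
        return counts
    candidates = [
        b for b in library.barcode_ids if b not in expected and b != library.reference_id
    ]
    if not candidates:
        logger.debug("no contamination targets for %s; counts unchanged", counts.sample_id)
        return counts
    total = int(counts.reads.sum())
    n_contam = rng.binomial(total, rate)
    if n_contam == 0:
        return AssayCounts(
            counts.sample_id, list(counts.barcodes), counts.reads.copy(), counts.depth, rate
        )
    # choose which physical reads get reassigned (without replacement)
    removed = rng.multivariate_hypergeometric(counts.reads.astype(np.int64), n_contam)
    new_reads = counts.reads - removed
    landed = rng.multinomial(n_contam, np.full(len(candidates), 1.0 / len(candidates)))
    index = {b: i for i, b in enumerate(counts.barcodes)}
    barcodes = list(counts.barcodes)
    new_reads = list(new_reads)
    for b, extra in zip(candidates, landed):
        if extra == 0:
            continue
        if b in index:
            new_reads[index[b]] += extra
        else:
            barcodes.append(b)
            new_reads.append(extra)
    return AssayCounts(
        sample_id=counts.sample_id,
        barcodes=barcodes,
        reads=np.asarray(new_reads, dtype=np.int64),
        depth=counts.depth,
        contamination_rate=rate,
    )


# ------------------------------------------------------------------ experiment


@dataclass
class SimulatedExperiment:
    """Everything the downstream pipeline needs, plus the generating truth."""

    design: ExperimentalDesign
    library: BarcodeLibrary
    sheet: SampleSheet
    counts: pd.DataFrame
    truth: TrueFitnessModel
    seed: int


def _make_indices(n: int, rng: np.random.Generator, layout: ReadLayout) -> list[tuple[str, str]]:
    bases = np.array(list("ACGT"))
    pairs: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    while len(out) < n:
        flen = int(rng.integers(layout.min_index_length, layout.max_index_length + 1))
        rlen = int(rng.integers(layout.min_index_length, layout.max_index_length + 1))
        pair = (
            "".join(rng.choice(bases, size=flen)),
            "".join(rng.choice(bases, size=rlen)),
        )
        if pair not in pairs:
            pairs.add(pair)
            out.append(pair)
    return out


def simulate_experiment(
    design: ExperimentalDesign,
    truth: TrueFitnessModel,
    depth: int = 100_000,
    seed: int = 0,
    contamination: float = 0.0,
    sentinels_per_set: int = 2,
    replicate_noise_sd: float = 0.0,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> SimulatedExperiment:
    """Simulate every sequencing sample of the competition-assay campaign.

    Pools: one Day-0 template pool (the ancestral strains, fitness 1
    everywhere) assayed in every chemical x stress-fraction environment, and
    one Day-50 pool per plate assayed in its own chemical's environments.
    Each (pool, environment) contributes ``initial_measure_replicates``
    0-hour samples and ``assay_replicates`` 48-hour samples.  Sentinel wells
    seeded with a single barcode pair track cross-contamination
    (``sentinels_per_set`` per set: Day-0, Day-50 per chemical).

    ``replicate_noise_sd`` adds lognormal biological noise to each lineage's
    realized fitness per 48-hour replicate (s.d. on the ln *w* scale).
    """
    ss = np.random.SeedSequence([int(seed), 0x51A55A])
    rng_idx, rng_counts, rng_cont = [np.random.default_rng(s) for s in ss.spawn(3)]

    lay = ancestral_layout(design)
    barcodes = list(lay["barcode"])
    n_b = len(barcodes)
    library = make_library(n_b, seed=seed)
    ref = library.reference_id

    pool_members = [ref] + barcodes
    spike = design.reference_spike_fraction
    f0 = np.array([spike] + [(1.0 - spike) / n_b] * n_b)

    # enumerate pools: Day-0 template assayed in all environments of all
    # chemicals; Day-50 plate pools in their own chemical's environments
    pools: list[tuple[str, int, str, str | None]] = []  # (pool_id, day, chemical, plate)
    for chem in design.chemicals:
        pools.append(("D0", 0, chem, None))
    for chem in design.chemicals:
        for plate_idx in range(design.plates_per_chemical):
            plate = f"{chem}{plate_idx + 1}"
            pools.append((plate, 50, chem, plate))

    sheet_rows: list[dict] = []
    count_frames: list[pd.DataFrame] = []

    def add_sample(sample_id, day, chem, frac, tp, rep, pool_id, sentinel, expected, reads_by_bc):
        sheet_rows.append(
            dict(
                sample_id=sample_id,
                day=day,
                chemical=chem,
                stress_fraction=frac,
                timepoint_h=tp,
                replicate=rep,
                pool_id=pool_id,
                sentinel=sentinel,
                expected_barcodes=";".join(sorted(expected)) if sentinel else "",
            )
        )
        count_frames.append(reads_by_bc)

    for pool_id, day, chem, plate in pools:
        expected = set(pool_members)
        for frac in design.assay_fractions:
            if plate is None:
                w_env = np.ones(n_b)
            else:
                w_env = truth.w50(plate, frac).reindex(barcodes).to_numpy()
            w_full = np.concatenate(([1.0], w_env))
            f48 = replicator_expectation(f0, w_full, generations=20.0)
            base = f"{pool_id}_{chem}{int(round(frac * 100))}"
            for rep in range(1, design.initial_measure_replicates + 1):
                sid = f"{base}_T0_r{rep}"
                c0 = rng_counts.multinomial(int(depth), f0)
                ac = AssayCounts(sid, pool_members, c0.astype(np.int64), int(depth))
                ac = inject_contamination(ac, contamination, library, expected, rng_cont)
                add_sample(sid, day, chem, frac, 0, rep, pool_id, False, expected, ac.to_frame())
            for rep in range(1, design.assay_replicates + 1):
                sid = f"{base}_T48_r{rep}"
                if replicate_noise_sd > 0:
                    eta = rng_counts.normal(0.0, replicate_noise_sd, size=n_b)
                    w_rep = np.concatenate(([1.0], w_env * np.exp(eta)))
                    f48_rep = replicator_expectation(f0, w_rep, generations=20.0)
                else:
                    f48_rep = f48
                c48 = rng_counts.multinomial(int(depth), f48_rep)
                ac = AssayCounts(sid, pool_members, c48.astype(np.int64), int(depth))
                ac = inject_contamination(ac, contamination, library, expected, rng_cont)
                add_sample(sid, day, chem, frac, 48, rep, pool_id, False, expected, ac.to_frame())

    # sentinel wells: a single barcode pair per well, no reference spike
    sentinel_sets = [(0, design.chemicals[0])] + [(50, chem) for chem in design.chemicals]
    pair_pool = lay.groupby(["treatment", "population_slot"], sort=False)["barcode"].apply(list)
    pair_list = list(pair_pool)
    k = 0
    for day, chem in sentinel_sets:
        for j in range(sentinels_per_set):
            pair = pair_list[k % len(pair_list)]
            k += 1
            sid = f"sentinel_d{day}_{chem}_{j + 1}"
            c = rng_counts.multinomial(int(depth), np.full(len(pair), 1.0 / len(pair)))
            ac = AssayCounts(sid, list(pair), c.astype(np.int64), int(depth))
            ac = inject_contamination(ac, contamination, library, set(pair), rng_cont)
            add_sample(sid, day, chem, 0.0, 0, j + 1, sid, True, set(pair), ac.to_frame())

    # assign index pairs
    pairs = _make_indices(len(sheet_rows), rng_idx, layout)
    for row, (fwd, rev) in zip(sheet_rows, pairs):
        row["fwd_index"] = fwd
        row["rev_index"] = rev

    sheet = SampleSheet(pd.DataFrame(sheet_rows)[SHEET_COLUMNS], layout=layout)
    counts = pd.concat(count_frames, ignore_index=True)[COUNT_COLUMNS]
    return SimulatedExperiment(
        design=design, library=library, sheet=sheet, counts=counts, truth=truth, seed=int(seed)
    )


# ------------------------------------------------------------------ FASTQ output


def write_fastq(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    library: BarcodeLibrary,
    path,
    seed: int = 0,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> int:
    """Emit one FASTQ record per counted read, in seed-shuffled order.

    Each read is [forward index][anchor][barcode 20-mer][anchor][reverse
    index] with a constant placeholder quality string.  Returns the number of
    records written.  ``.gz`` paths are gzip-compressed.
    """
    idx_by_sample = {
        r.sample_id: (str(r.fwd_index), str(r.rev_index)) for r in sheet.df.itertuples()
    }
    seqs = library.sequences

    templates: list[str] = []
    reps: list[int] = []
    for r in counts.itertuples():
        n = int(r.reads) if pd.notna(r.reads) else 0
        if n <= 0:
            continue
        if r.sample_id not in idx_by_sample:
            raise SimulationError(f"sample {r.sample_id!r} missing from sample sheet")
        if r.barcode not in seqs:
            raise SimulationError(f"barcode {r.barcode!r} absent from library")
        fwd, rev = idx_by_sample[r.sample_id]
        templates.append(layout.assemble(fwd, seqs[r.barcode], rev))
        reps.append(n)

    total = int(np.sum(reps)) if reps else 0
    order = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA57])).permutation(total)
    expanded = np.repeat(np.arange(len(templates)), reps) if templates else np.array([], dtype=int)
    expanded = expanded[order]

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, t_idx in enumerate(expanded):
            seq = templates[t_idx]
            fh.write(f"@read_{i:08d}\n{seq}\n+\n{'I' * len(seq)}\n")
    return total
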
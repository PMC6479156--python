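"""Prioritization core: within-region rescaling, weighted summation,
threshold quantization, the coverage-vs-area fitness function, and the
genetic algorithm that searches over the four variable weights plus the
quantization threshold.

The fitness of a candidate model is

    (r + pl + e + pe) / 4  -  a / A

where r is the fraction of species with at least one selected occupied cell,
pl the captured fraction of total branch length, e the captured fraction of
total weighted-endemism index, pe the captured fraction of total
phylogenetic-endemism weight, a the number of selected cells and A the
total number of cells under analysis.  A model that captures everything in
a vanishing area scores close to 1; selecting the whole study area scores
exactly 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import HexGrid, OccurrenceTable, PresenceMatrix, Surface, assign_cells, assign_records
from .metrics import (
    ResampleConfig,
    gie_consensus,
    richness_resampled,
    species_dispersion,
    species_we,
    weighted_endemism,
)
from .phylo import EdgeTable, branch_incidence, pwe_surface
from .regionalize import RegionMap, classify_regions
from .spatial import KrigingConfig, beta_phylosor, beta_sorensen, composition_surfaces, krige, nmds

logger = logging.getLogger(__name__)

SURFACE_ORDER = ("richness", "endemism", "aoe", "pe")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genome:
    """A candidate model: four variable weights plus the quantization threshold."""

    w_richness: float
    w_endemism: float
    w_aoe: float
    w_pe: float
    threshold: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"allele {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_richness, self.w_endemism, self.w_aoe, self.w_pe, self.threshold])

    def as_dict(self) -> dict[str, float]:
        return {
            "w_richness": self.w_richness,
            "w_endemism": self.w_endemism,
            "w_aoe": self.w_aoe,
            "w_pe": self.w_pe,
            "threshold": self.threshold,
        }

    @classmethod
    def from_array(cls, arr) -> "Genome":
        return cls(*(float(x) for x in np.asarray(arr, float)))


PRIMEVAL = Genome(0.5, 0.5, 0.5, 0.5, 0.5)


# ---------------------------------------------------------------------------
# Surface algebra
# ---------------------------------------------------------------------------


def rescale_within_regions(surface: Surface, regions: RegionMap) -> Surface:
    """Min-max rescale the surface to [0, 1] independently inside each region.

    Constant regions rescale to all zeros (warned); no-data and out-of-region
    cells stay no-data.
    """
    out = Surface.full(surface.grid)
    for r in range(1, regions.k + 1):
        cells = (regions.labels == r) & surface.mask
        if not cells.any():
            continue
        v = surface.values[cells]
        lo, hi = float(v.min()), float(v.max())
        if hi > lo:
            out.values[cells] = (v - lo) / (hi - lo)
        else:
            warnings.warn(f"region {r}: constant surface, rescaled to 0")
            out.values[cells] = 0.0
    return out


def weighted_sum(surfaces: dict[str, Surface], genome: Genome) -> Surface:
    """Weighted sum of the four rescaled variable surfaces, then min-max
    rescaled to [0, 1] globally so the threshold allele is comparable across
    genomes.  All-zero weights give an all-zero surface (warned)."""
    missing = [k for k in SURFACE_ORDER if k not in surfaces]
    if missing:
        raise ValueError(f"missing surfaces {missing}")
    grid = surfaces[SURFACE_ORDER[0]].grid
    w = np.array([genome.w_richness, genome.w_endemism, genome.w_aoe, genome.w_pe])
    stack = np.column_stack([surfaces[k].values for k in SURFACE_ORDER])
    joint = np.isfinite(stack).all(axis=1)
    vals = np.full(grid.n_cells, np.nan)
    if w.sum() == 0:
        warnings.warn("all weights are zero; weighted sum is identically 0")
        vals[joint] = 0.0
        return Surface(grid, vals)
    s = stack[joint] @ w
    lo, hi = float(s.min()), float(s.max())
    vals[joint] = (s - lo) / (hi - lo) if hi > lo else 0.0
    return Surface(grid, vals)


def quantize(surface: Surface, threshold: float) -> np.ndarray:
    """Binary relevance map: selected iff value >= threshold (no-data never)."""
    return surface.mask & (np.nan_to_num(surface.values, nan=-np.inf) >= threshold)


# ---------------------------------------------------------------------------
# Fitness inputs and coverage fractions
# ---------------------------------------------------------------------------


@dataclass
class FitnessInputs:
    """Grid-wide totals and incidences the coverage fractions are scored on.

    ``capture_mode="species"`` counts a species' (or branch's) full endemism
    weight as captured once any of its occupied cells is selected;
    ``"cell_sum"`` instead sums the per-cell endemism surfaces over selected
    cells.
    """

    cell_ids: np.ndarray  # occupied cells (rows of the presence matrix)
    species_cells: np.ndarray  # (n_occ_cells, S) bool
    we_s: np.ndarray  # (S,) weighted-endemism index per species
    branch_occ: np.ndarray  # (B, n_occ_cells) bool
    branch_len: np.ndarray  # (B,)
    branch_we: np.ndarray  # (B,) L_b / R_b
    total_cells: int  # A in the fitness function
    capture_mode: str = "species"
    we_cell: np.ndarray | None = None  # per-occupied-cell WE sum (cell_sum mode)
    pwe_cell: np.ndarray | None = None

    def __post_init__(self):
        if self.total_cells < 1:
            raise ValueError("total_cells must be >= 1")
        if self.capture_mode not in ("species", "cell_sum"):
            raise ValueError("capture_mode must be 'species' or 'cell_sum'")
        if self.branch_len.sum() <= 0 or self.we_s.sum() <= 0:
            raise ValueError("fitness totals must be strictly positive")


def build_fitness_inputs(
    presence: PresenceMatrix,
    tree,
    grid: HexGrid,
    total_cells: int | None = None,
    capture_mode: str = "species",
) -> FitnessInputs:
    et = tree if isinstance(tree, EdgeTable) else EdgeTable.from_tree(tree)
    occ, _ = branch_incidence(presence, et)
    r_b = occ.sum(axis=1).astype(float)
    present = r_b > 0
    occ, lens = occ[present], et.lengths[present]
    branch_we = lens / r_b[present]
    sp_cells = presence.data.to_numpy()
    we = species_we(presence).to_numpy()
    return FitnessInputs(
        cell_ids=presence.cell_ids.astype(int),
        species_cells=sp_cells,
        we_s=we,
        branch_occ=occ,
        branch_len=lens,
        branch_we=branch_we,
        total_cells=int(total_cells if total_cells is not None else grid.n_cells),
        capture_mode=capture_mode,
        we_cell=sp_cells @ we,
        pwe_cell=branch_we @ occ,
    )


@dataclass(frozen=True)
class CoverageFractions:
    r: float
    pl: float
    e: float
    pe: float
    area_fraction: float


def coverage_fractions(selected: np.ndarray, inputs: FitnessInputs) -> CoverageFractions:
    """Captured fractions of species, branch length, endemism weight and
    phylogenetic endemism weight for a binary cell selection, plus the
    selected-area fraction a/A."""
    selected = np.asarray(selected, bool)
    sel_occ = selected[inputs.cell_ids]
    sp_hit = inputs.species_cells[sel_occ].any(axis=0) if sel_occ.any() else np.zeros(inputs.species_cells.shape[1], bool)
    br_hit = inputs.branch_occ[:, sel_occ].any(axis=1) if sel_occ.any() else np.zeros(len(inputs.branch_len), bool)
    r = float(sp_hit.sum()) / inputs.species_cells.shape[1]
    pl = float(inputs.branch_len[br_hit].sum()) / float(inputs.branch_len.sum())
    if inputs.capture_mode == "species":
        e = float(inputs.we_s[sp_hit].sum()) / float(inputs.we_s.sum())
        pe = float(inputs.branch_we[br_hit].sum()) / float(inputs.branch_we.sum())
    else:
        e = float(inputs.we_cell[sel_occ].sum()) / float(inputs.we_cell.sum())
        pe = float(inputs.pwe_cell[sel_occ].sum()) / float(inputs.pwe_cell.sum())
    area = float(selected.sum()) / inputs.total_cells
    return CoverageFractions(r=r, pl=pl, e=e, pe=pe, area_fraction=area)


@dataclass
class FitnessResult:
    value: float
    r: float
    pl: float
    e: float
    pe: float
    area_fraction: float
    selected_cells: np.ndarray
    genome: Genome | None = None

    def __post_init__(self):
        expect = (self.r + self.pl + self.e + self.pe) / 4.0 - self.area_fraction
        assert abs(self.value - expect) < 1e-9, "fitness value inconsistent with its parts"


class FitnessEvaluator:
    """Precomputes the genome-independent stages of the fitness pipeline.

    Within-region rescaling depends only on the surfaces and the region map,
    so it is done once; each genome evaluation is then a weighted sum, a
    global rescale, a threshold cut, and the coverage tally.
    """

    def __init__(self, surfaces: dict[str, Surface], regions: RegionMap, inputs: FitnessInputs):
        self.regions = regions
        self.inputs = inputs
        self.rescaled = {k: rescale_within_regions(s, regions) for k, s in surfaces.items()}

    def evaluate(self, genome: Genome) -> FitnessResult:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            combined = weighted_sum(self.rescaled, genome)
        selected = quantize(combined, genome.threshold)
        cov = coverage_fractions(selected, self.inputs)
        value = (cov.r + cov.pl + cov.e + cov.pe) / 4.0 - cov.area_fraction
        return FitnessResult(
            value=value,
            r=cov.r,
            pl=cov.pl,
            e=cov.e,
            pe=cov.pe,
            area_fraction=cov.area_fraction,
            selected_cells=np.nonzero(selected)[0],
            genome=genome,
        )

    def __call__(self, genome: Genome) -> float:
        return self.evaluate(genome).value


def fitness(genome: Genome, surfaces: dict[str, Surface], regions: RegionMap, inputs: FitnessInputs) -> FitnessResult:
    """One-shot fitness evaluation (rescale, weighted sum, quantize, score)."""
    return FitnessEvaluator(surfaces, regions, inputs).evaluate(genome)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    pop_size: int = 20
    max_generations: int = 100
    elite_fraction: float = 0.25
    random_pick_fraction: float = 0.15
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sd: float = 0.1
    stall_generations: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for name in ("elite_fraction", "random_pick_fraction", "crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GAResult:
    best_genome: Genome
    best_fitness: float
    history: pd.DataFrame  # per generation: best, mean
    n_generations: int


def ga_optimize(objective, cfg: GAConfig | None = None) -> GAResult:
    """Maximize ``objective(Genome) -> float`` over [0, 1]^5.

    Individual 0 of the initial population is the primeval genome
    (0.5, 0.5, 0.5, 0.5, 0.5); the rest are uniform in the bounds.  Each
    generation keeps the top-ranked elites plus a random pick of the
    remainder, refills by uniform crossover of selected parents followed by
    clipped Gaussian mutation, and stops at ``max_generations`` or after
    ``stall_generations`` without improvement.  Elitism guarantees the best
    solution is never lost and the best-fitness history is nondecreasing.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.pop_size, 5
    pop = rng.uniform(0.0, 1.0, size=(n, k))
    pop[0] = PRIMEVAL.as_array()
    fit = np.array([objective(Genome.from_array(g)) for g in pop])
    best_idx = int(np.argmax(fit))
    best_g, best_f = pop[best_idx].copy(), float(fit[best_idx])
    rows = [{"generation": 0, "best": best_f, "mean": float(fit.mean())}]
    stall = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        order = np.argsort(-fit, kind="stable")
        n_elite = max(1, int(round(cfg.elite_fraction * n)))
        n_rand = int(round(cfg.random_pick_fraction * n))
        rest = order[n_elite:]
        picks = rng.choice(rest, size=min(n_rand, len(rest)), replace=False) if len(rest) and n_rand else np.array([], int)
        sel = np.vstack([pop[order[:n_elite]], pop[picks]]) if len(picks) else pop[order[:n_elite]]
        children = []
        while len(sel) + len(children) < n:
            pa, pb = sel[rng.integers(0, len(sel), size=2)]
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(k) < 0.5
                child = np.where(mask, pa, pb)
            else:
                child = pa.copy()
            mut = rng.random(k) < cfg.mutation_rate
            child = np.clip(child + np.where(mut, rng.normal(0.0, cfg.mutation_sd, k), 0.0), 0.0, 1.0)
            children.append(child)
        pop = np.vstack([sel] + children) if children else sel
        fit = np.array([objective(Genome.from_array(g)) for g in pop])
        gen_best = float(fit.max())
        if gen_best > best_f:
            best_f = gen_best
            best_g = pop[int(np.argmax(fit))].copy()
            stall = 0
        else:
            stall += 1
        rows.append({"generation": gen, "best": best_f, "mean": float(fit.mean())})
        if stall >= cfg.stall_generations:
            break
    history = pd.DataFrame(rows)
    return GAResult(
        best_genome=Genome.from_array(best_g),
        best_fitness=best_f,
        history=history,
        n_generations=gen,
    )


# ---------------------------------------------------------------------------
# Experiment harness: full model, taxonomic surrogates, no-phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PipelineSettings:
    """All tunables of the surface-building + regionalization + GA pipeline."""

    resample: ResampleConfig = field(default_factory=ResampleConfig)
    kriging: KrigingConfig = field(default_factory=KrigingConfig)
    ndim_composition: int = 3
    nmds_rounds: int = 20
    min_records: int = 5
    n_regions: int | str = "auto"
    k_range: tuple[int, int] = (2, 8)
    ga: GAConfig = field(default_factory=GAConfig)
    capture_mode: str = "species"
    seed: int = 0

    def reseed(self, seed: int) -> "PipelineSettings":
        return replace(
            self,
            seed=seed,
            resample=replace(self.resample, seed=seed + 1),
            kriging=replace(self.kriging, seed=seed + 2),
            ga=replace(self.ga, seed=seed + 3),
        )


@dataclass
class ExperimentResult:
    mode: str
    genome: Genome
    fitness_result: FitnessResult
    history: pd.DataFrame
    regions: RegionMap
    surfaces: dict[str, Surface]
    ordination_stress: dict[str, float]

    def summary(self) -> dict[str, float]:
        fr = self.fitness_result
        return {
            "mode": self.mode,
            "fitness": fr.value,
            "species_fraction": fr.r,
            "lineage_fraction": fr.pl,
            "endemism_fraction": fr.e,
            "phylo_endemism_fraction": fr.pe,
            "area_fraction": fr.area_fraction,
            **{f"weight_{k}": v for k, v in self.genome.as_dict().items()},
        }


def _krige_surface(surface: Surface, grid: HexGrid, cfg: KrigingConfig) -> Surface:
    """Interpolate a partially observed surface from its unmasked cells."""
    m = surface.mask
    if m.all():
        return surface
    return krige(grid.centers[m, 0], grid.centers[m, 1], surface.values[m], grid, cfg).mean


def build_variable_surfaces(
    table: OccurrenceTable, grid: HexGrid, tree, settings: PipelineSettings
) -> dict[str, Surface]:
    """The four quantitative variable surfaces (richness, endemism, areas of
    endemism, phylogenetic endemism), effort-corrected and interpolated."""
    presence = assign_cells(table, grid)
    rich = richness_resampled(table, grid, settings.resample)
    we = weighted_endemism(presence, grid)
    aoe = gie_consensus(species_dispersion(table), grid)
    pwe = pwe_surface(presence, tree, grid)
    return {
        "richness": _krige_surface(rich, grid, settings.kriging),
        "endemism": _krige_surface(we, grid, settings.kriging),
        "aoe": aoe,
        "pe": _krige_surface(pwe, grid, settings.kriging),
    }


def build_composition_surfaces(
    table: OccurrenceTable,
    grid: HexGrid,
    tree,
    settings: PipelineSettings,
    include_phylo: bool = True,
) -> tuple[list[Surface], dict[str, float]]:
    """SCI (+ optionally IPC) composition surfaces: beta-diversity matrices,
    NMDS ordination, and kriging of the ordination axes."""
    presence = assign_cells(table, grid)
    rec = assign_records(table, grid)
    counts = rec.groupby("cell_id").size()
    stresses: dict[str, float] = {}
    out: list[Surface] = []
    d_sor = beta_sorensen(presence, settings.min_records, counts)
    ord_sci = nmds(d_sor, ndim=settings.ndim_composition, n_rounds=settings.nmds_rounds, seed=settings.seed)
    stresses["sci"] = ord_sci.stress
    out.extend(composition_surfaces(ord_sci, grid, settings.kriging))
    if include_phylo:
        d_ps = beta_phylosor(presence, tree, settings.min_records, counts)
        ord_ipc = nmds(d_ps, ndim=settings.ndim_composition, n_rounds=settings.nmds_rounds, seed=settings.seed + 17)
        stresses["ipc"] = ord_ipc.stress
        out.extend(composition_surfaces(ord_ipc, grid, settings.kriging))
    return out, stresses


def run_experiment(
    mode: str,
    table: OccurrenceTable,
    grid: HexGrid,
    tree,
    settings: PipelineSettings | None = None,
) -> ExperimentResult:
    """Run the full prioritization for one evaluation mode.

    ``mode`` is ``"all_groups"``, ``"surrogate:<group>"`` (surfaces and
    regionalization built from one taxonomic group only), or ``"no_phylo"``
    (phylogenetic composition dropped from regionalization and phylogenetic
    endemism dropped from the weighted sum).  Whatever the mode, the fitness
    is always scored against all groups and all dimensions, including the
    phylogenetic ones.
    """
    settings = settings or PipelineSettings()
    if mode == "all_groups":
        source, include_phylo = table, True
    elif mode == "no_phylo":
        source, include_phylo = table, False
    elif mode.startswith("surrogate:"):
        source, include_phylo = table.subset_group(mode.split(":", 1)[1]), True
    else:
        raise ValueError(f"unknown mode {mode!r}")

    surfaces = build_variable_surfaces(source, grid, tree, settings)
    if not include_phylo:
        surfaces["pe"] = Surface(grid, np.zeros(grid.n_cells))
    comp, stresses = build_composition_surfaces(source, grid, tree, settings, include_phylo)
    regions = classify_regions(comp, k=settings.n_regions, seed=settings.seed, k_range=settings.k_range)

    presence_all = assign_cells(table, grid)
    inputs = build_fitness_inputs(presence_all, tree, grid, capture_mode=settings.capture_mode)
    evaluator = FitnessEvaluator(surfaces, regions, inputs)
    ga_res = ga_optimize(evaluator, settings.ga)
    final = evaluator.evaluate(ga_res.best_genome)
    logger.info("mode %s: fitness %.3f in %.1f%% of cells", mode, final.value, 100 * final.area_fraction)
    return ExperimentResult(
        mode=mode,
        genome=ga_res.best_genome,
        fitness_result=final,
        history=ga_res.history,
        regions=regions,
        surfaces=surfaces,
        ordination_stress=stresses,
    )


def compare_experiments(results: list[ExperimentResult]) -> pd.DataFrame:
    """One row per mode: fitness, coverage fractions, area, and weights."""
    return pd.DataFrame([r.summary() for r in results])
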
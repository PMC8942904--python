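"""Synthetic breeding-program generator.

Emulates the data-generating process assumed by the downstream models: inbred
lines derived from bi-parental crosses followed by single-seed-descent selfing,
multi-cycle multi-location yield trials laid out in blocks on a rectangular
grid, with additive and pairwise additive-by-additive marker effects, an
uncorrelated per-line effect, line-by-environment interaction, 9-plot spatial
effects (including a virtual border ring), and i.i.d. residuals.

Every stochastic step is driven by :class:`numpy.random.Generator` streams
spawned from a single seed, so identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (ConfigurationError, DegenerateArchitectureError,
                     InputError, LayoutError)

logger = logging.getLogger(__name__)

__all__ = [
    "BreedingProgramConfig",
    "GeneticArchitecture",
    "TrueGeneticValues",
    "SimulationResult",
    "simulate_founders",
    "simulate_cross_and_ssd",
    "assign_genetic_effects",
    "simulate_field_trials",
    "inject_missing",
    "simulate_breeding_program",
    "export_simulation",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class BreedingProgramConfig:
    """Design of the simulated breeding program.

    Defaults mirror the study design downstream models assume: F6 lines after
    five selfing generations, trials of 15 blocks with 46 plots each (two
    replicates of 21 lines plus two checks replicated twice), ~1.3% missing
    genotype calls, and yields around a grand mean of 8.71 kg per plot.
    """

    n_founders: int = 20
    n_crosses: int = 10
    lines_per_cross: int = 40
    n_selfing_generations: int = 5
    n_markers: int = 500
    founder_maf_distribution: tuple[float, float] = (0.1, 0.5)
    n_cycles: int = 1
    years_per_cycle: int = 1
    locations_per_year: int = 3
    blocks_per_trial: int = 15
    lines_per_block: int = 21
    replicates_per_line_in_block: int = 2
    n_checks_per_block: int = 2
    missing_genotype_rate: float = 0.013
    random_seed: int = 0
    # Phenotype scale (kg / 8.25 m^2 plot); magnitudes irrelevant to the
    # variance structure but realistic for demos.
    grand_mean: float = 8.71
    trial_effect_sd: float = 0.5
    # When False each breeding cycle is founded on a disjoint founder pool, so
    # cycles are genetically unrelated (the across-cycle validation scenario).
    shared_founders: bool = True

    @property
    def plots_per_block(self) -> int:
        return (self.lines_per_block * self.replicates_per_line_in_block
                + self.n_checks_per_block * 2)

    @property
    def lines_per_cycle(self) -> int:
        return self.blocks_per_trial * self.lines_per_block

    @property
    def n_lines_required(self) -> int:
        return self.n_cycles * self.lines_per_cycle + self.n_checks_per_block

    def validate(self) -> None:
        counts = ["n_founders", "n_crosses", "lines_per_cross", "n_markers",
                  "n_cycles", "years_per_cycle", "locations_per_year",
                  "blocks_per_trial", "lines_per_block",
                  "replicates_per_line_in_block"]
        for name in counts:
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2 to form a cross")
        if self.n_checks_per_block < 0:
            raise ConfigurationError("n_checks_per_block must be >= 0")
        if self.n_selfing_generations < 0:
            raise ConfigurationError("n_selfing_generations must be >= 0")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ConfigurationError(
                f"missing_genotype_rate must be in [0, 1), got {self.missing_genotype_rate}")
        lo, hi = self.founder_maf_distribution
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"founder_maf_distribution must satisfy 0 < lo <= hi <= 0.5, got {self.founder_maf_distribution}")
        if self.n_crosses * self.lines_per_cross < self.n_lines_required:
            raise ConfigurationError(
                f"n_crosses * lines_per_cross = {self.n_crosses * self.lines_per_cross} "
                f"lines cannot fill {self.n_cycles} cycle(s) of "
                f"{self.lines_per_cycle} lines plus {self.n_checks_per_block} checks")
        if not self.shared_founders and self.n_founders < 2 * self.n_cycles:
            raise ConfigurationError(
                "shared_founders=False needs at least 2 founders per cycle")


@dataclass
class GeneticArchitecture:
    """True genetic architecture: QTL counts and target plot-scale variances.

    ``target_variances`` keys: ``additive`` (sigma_g^2), ``epistatic``
    (sigma_h^2), ``line`` (sigma_l^2, per-line effect not carried by markers),
    ``gxe`` (sigma_f^2), ``spatial`` (sigma_s^2, per grid position), ``error``
    (sigma_e^2). Missing keys default to 0.
    """

    n_additive_qtl: int = 100
    n_epistatic_pairs: int = 100
    target_variances: dict = field(default_factory=dict)
    effect_distribution: str = "normal"

    def variance(self, name: str) -> float:
        return float(self.target_variances.get(name, 0.0))

    def validate(self, n_markers: int | None = None) -> None:
        for key, value in self.target_variances.items():
            if value < 0:
                raise ConfigurationError(f"target variance {key!r} must be >= 0, got {value}")
        if self.n_additive_qtl < 0 or self.n_epistatic_pairs < 0:
            raise ConfigurationError("QTL counts must be >= 0")
        if n_markers is not None and self.n_additive_qtl > n_markers:
            raise ConfigurationError(
                f"n_additive_qtl = {self.n_additive_qtl} exceeds n_markers = {n_markers}")
        if self.effect_distribution != "normal":
            raise ConfigurationError(
                f"unsupported effect_distribution {self.effect_distribution!r}")


@dataclass
class TrueGeneticValues:
    """Ground-truth genetic values per line (simulation oracle)."""

    values: pd.DataFrame  # index line_id; columns additive, epistatic, total
    additive_effects: pd.Series  # per sampled QTL marker
    epistatic_effects: pd.DataFrame  # columns marker_1, marker_2, effect
    rescale_factors: dict


# ---------------------------------------------------------------------------
# Founders, crosses, and single-seed descent
# ---------------------------------------------------------------------------

def _line_ids(n: int, prefix: str = "L") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_founders(config: BreedingProgramConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fully homozygous founder genotypes with entries in {0, 2}.

    Per-marker allele frequencies are drawn uniformly from
    ``founder_maf_distribution``; each founder's genotype at a marker is then
    2 x Bernoulli(p).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    freqs = rng.uniform(*config.founder_maf_distribution, size=config.n_markers)
    geno = 2 * (rng.random((config.n_founders, config.n_markers)) < freqs)
    markers = [f"M{j + 1:05d}" for j in range(config.n_markers)]
    return pd.DataFrame(geno.astype(float), index=_line_ids(config.n_founders, "F"),
                        columns=markers)


def simulate_cross_and_ssd(founders: pd.DataFrame,
                           config: BreedingProgramConfig,
                           rng: np.random.Generator | None = None,
                           cross_pairs: list[tuple[int, int]] | None = None,
                           lines_per_cross: int | None = None,
                           id_offset: int = 0,
                           id_total: int | None = None,
                           ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Bi-parental crosses followed by single-seed-descent selfing.

    Markers segregate independently (no linkage map): at each selfing
    generation a heterozygous locus resolves to either homozygote with
    probability 1/4 each and stays heterozygous with probability 1/2.

    Returns the line genotypes (allele counts in {0, 1, 2}), realized
    heterozygosity per line (fraction of markers with genotype 1), and the
    cross index of each line.
    """
    if founders.shape[0] < 2:
        raise InputError("at least 2 founders are required for a cross")
    values = founders.to_numpy()
    if not np.isin(values, (0.0, 2.0)).all():
        raise InputError("founders must be fully homozygous (entries in {0, 2})")
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    if lines_per_cross is None:
        lines_per_cross = config.lines_per_cross
    if cross_pairs is None:
        cross_pairs = []
        for _ in range(config.n_crosses):
            i, j = rng.choice(founders.shape[0], size=2, replace=False)
            cross_pairs.append((int(i), int(j)))

    n_lines = len(cross_pairs) * lines_per_cross
    rows = []
    cross_of = []
    for c, (i, j) in enumerate(cross_pairs):
        f1 = (values[i] + values[j]) / 2.0  # deterministic: parents homozygous
        block = np.tile(f1, (lines_per_cross, 1))
        rows.append(block)
        cross_of.extend([c] * lines_per_cross)
    geno = np.vstack(rows)

    for _ in range(config.n_selfing_generations):
        het = geno == 1.0
        if not het.any():
            break
        u = rng.random(size=int(het.sum()))
        resolved = np.ones_like(u)
        resolved[u < 0.25] = 0.0
        resolved[u >= 0.75] = 2.0
        geno[het] = resolved

    total = id_total if id_total is not None else n_lines
    ids = _line_ids(total)[id_offset:id_offset + n_lines]
    geno_df = pd.DataFrame(geno, index=ids, columns=founders.columns)
    het = pd.Series((geno == 1.0).mean(axis=1), index=ids, name="heterozygosity")
    cross = pd.Series(cross_of, index=ids, name="cross")
    return geno_df, het, cross


# ---------------------------------------------------------------------------
# Genetic effects
# ---------------------------------------------------------------------------

def _rescale(values: np.ndarray, target: float, what: str,
             factors: dict) -> np.ndarray:
    """Scale effect outcomes so the realized line variance equals the target."""
    if target == 0.0:
        factors[what] = 0.0
        return np.zeros_like(values)
    realized = values.var(ddof=1)
    if realized <= 0.0:
        raise DegenerateArchitectureError(
            f"target {what} variance {target} requested but realized variance is zero "
            "(monomorphic QTL or empty architecture)")
    scale = np.sqrt(target / realized)
    factors[what] = float(scale)
    logger.info("rescaled %s effects by %.6g to reach variance %.6g", what, scale, target)
    return values * scale


def assign_genetic_effects(genotypes: pd.DataFrame,
                           arch: GeneticArchitecture,
                           seed: int | np.random.Generator = 0) -> TrueGeneticValues:
    """Sample QTL effects and compute true additive / epistatic line values.

    Additive value of line i is sum_j alpha_j x_ij over sampled QTL (x the
    allele count); the epistatic value is sum_(j,k) beta_jk w_ij w_ik over
    sampled unordered marker pairs, with w the column-centered allele count.
    Effects are rescaled so realized line variances match the targets exactly;
    the factors are recorded.
    """
    arch.validate(n_markers=genotypes.shape[1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = genotypes.to_numpy(dtype=float)
    n, m = X.shape
    factors: dict = {}

    if arch.n_additive_qtl > 0 and arch.variance("additive") > 0:
        qtl = np.sort(rng.choice(m, size=arch.n_additive_qtl, replace=False))
        alpha = rng.standard_normal(arch.n_additive_qtl)
        additive = X[:, qtl] @ alpha
        additive = _rescale(additive, arch.variance("additive"), "additive", factors)
        alpha = alpha * factors["additive"]
        add_effects = pd.Series(alpha, index=genotypes.columns[qtl], name="alpha")
    else:
        additive = np.zeros(n)
        factors["additive"] = 0.0
        add_effects = pd.Series(dtype=float, name="alpha")

    if arch.n_epistatic_pairs > 0 and arch.variance("epistatic") > 0:
        W = X - X.mean(axis=0, keepdims=True)
        pairs = set()
        while len(pairs) < arch.n_epistatic_pairs:
            j, k = rng.choice(m, size=2, replace=False)
            pairs.add((min(j, k), max(j, k)))
        pairs = sorted(pairs)
        beta = rng.standard_normal(len(pairs))
        epistatic = np.zeros(n)
        for (j, k), b in zip(pairs, beta):
            epistatic += b * W[:, j] * W[:, k]
        epistatic = _rescale(epistatic, arch.variance("epistatic"), "epistatic", factors)
        beta = beta * factors["epistatic"]
        epi_effects = pd.DataFrame({
            "marker_1": [genotypes.columns[j] for j, _ in pairs],
            "marker_2": [genotypes.columns[k] for _, k in pairs],
            "effect": beta,
        })
    else:
        epistatic = np.zeros(n)
        factors["epistatic"] = 0.0
        epi_effects = pd.DataFrame(columns=["marker_1", "marker_2", "effect"])

    values = pd.DataFrame({
        "additive": additive,
        "epistatic": epistatic,
        "total": additive + epistatic,
    }, index=genotypes.index)
    return TrueGeneticValues(values=values, additive_effects=add_effects,
                             epistatic_effects=epi_effects, rescale_factors=factors)


# ---------------------------------------------------------------------------
# Field trials
# ---------------------------------------------------------------------------

def _spatial_field(nx: int, ny: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Position effects on the (nx+2) x (ny+2) grid including the virtual ring."""
    return rng.normal(0.0, sd, size=(nx + 2, ny + 2))


def simulate_field_trials(lines: pd.DataFrame,
                          truth: TrueGeneticValues,
                          config: BreedingProgramConfig,
                          arch: GeneticArchitecture,
                          rng: np.random.Generator | None = None,
                          cycle_of: pd.Series | None = None,
                          check_ids: list[str] | None = None) -> pd.DataFrame:
    """Lay out trials and draw plot phenotypes from the generating model.

    Each trial (cycle x year x location) holds ``blocks_per_trial`` blocks of
    ``plots_per_block`` plots on a rectangular grid (x = block column,
    y = position within the block column). A plot's phenotype is

        trial effect + line effect + additive + epistatic
        + line-by-environment draw + sum of the 9 covering spatial effects
        + residual.

    Spatial effects live on a per-trial grid with a one-deep virtual ring; the
    virtual positions receive real draws but no phenotypes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    line_ids = list(lines.index)
    if check_ids is None:
        check_ids = line_ids[-config.n_checks_per_block:] if config.n_checks_per_block else []
    candidates = [lid for lid in line_ids if lid not in set(check_ids)]
    if cycle_of is None:
        need = config.n_cycles * config.lines_per_cycle
        if len(candidates) < need:
            raise InputError(
                f"{len(candidates)} candidate lines cannot fill {need} cycle slots")
        cycle_of = pd.Series(
            {lid: 1 + i // config.lines_per_cycle for i, lid in enumerate(candidates[:need])})

    sigma = {k: arch.variance(k) for k in ("line", "gxe", "spatial", "error")}
    line_effect = pd.Series(
        rng.normal(0.0, np.sqrt(sigma["line"]), size=len(line_ids)), index=line_ids)
    add = truth.values["additive"]
    epi = truth.values["epistatic"]

    nx, ny = config.blocks_per_trial, config.plots_per_block
    records = []
    plot_counter = 0
    for cycle in range(1, config.n_cycles + 1):
        cycle_lines = [lid for lid, c in cycle_of.items() if c == cycle]
        if len(cycle_lines) != config.lines_per_cycle:
            raise LayoutError(
                f"cycle {cycle} has {len(cycle_lines)} lines but the layout requires "
                f"exactly {config.lines_per_cycle} ({config.blocks_per_trial} blocks x "
                f"{config.lines_per_block} lines)")
        for year_i in range(config.years_per_cycle):
            year = 2013 + (cycle - 1) + year_i
            for loc_i in range(config.locations_per_year):
                location = f"LOC{loc_i + 1}"
                trial = f"C{cycle}_Y{year}_{location}"
                env = f"{year}_{location}"
                field_eff = _spatial_field(nx, ny, np.sqrt(sigma["spatial"]), rng)
                trial_effect = config.grand_mean + (
                    rng.normal(0.0, config.trial_effect_sd) if config.trial_effect_sd > 0 else 0.0)
                # re-randomize block membership per trial
                order = rng.permutation(len(cycle_lines))
                f_draw = {lid: rng.normal(0.0, np.sqrt(sigma["gxe"]))
                          for lid in cycle_lines + list(check_ids)}
                for b in range(config.blocks_per_trial):
                    members = [cycle_lines[order[b * config.lines_per_block + i]]
                               for i in range(config.lines_per_block)]
                    plot_lines = members * config.replicates_per_line_in_block \
                        + list(check_ids) * 2
                    is_check = [False] * (len(members) * config.replicates_per_line_in_block) \
                        + [True] * (len(check_ids) * 2)
                    shuffle = rng.permutation(len(plot_lines))
                    for y_pos, s in enumerate(shuffle):
                        lid = plot_lines[s]
                        x, ypos = b + 1, y_pos + 1
                        spatial = field_eff[x - 1:x + 2, ypos - 1:ypos + 2].sum()
                        resid = rng.normal(0.0, np.sqrt(sigma["error"]))
                        phenotype = (trial_effect + line_effect[lid] + add[lid]
                                     + epi[lid] + f_draw[lid] + spatial + resid)
                        plot_counter += 1
                        records.append({
                            "plot_id": f"P{plot_counter:06d}",
                            "line_id": lid,
                            "is_check": bool(is_check[s]),
                            "cycle": cycle,
                            "year": year,
                            "location": location,
                            "trial": trial,
                            "env": env,
                            "block": f"{trial}_B{b + 1}",
                            "x": x,
                            "y": ypos,
                            "yield_kg": phenotype,
                        })
    return pd.DataFrame.from_records(records)


def inject_missing(genotypes: pd.DataFrame, rate: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Set a completely-at-random fraction of genotype calls to missing."""
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError(f"missing rate must be in [0, 1), got {rate}")
    observed = genotypes.copy()
    if rate > 0:
        mask = rng.random(genotypes.shape) < rate
        observed = observed.mask(mask)
    return observed


# ---------------------------------------------------------------------------
# End-to-end program
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: BreedingProgramConfig
    arch: GeneticArchitecture
    founders: pd.DataFrame
    genotypes: pd.DataFrame           # clean allele counts
    genotypes_observed: pd.DataFrame  # with missing calls injected
    heterozygosity: pd.Series
    line_info: pd.DataFrame           # line_id index: cross, cycle, is_check
    truth: TrueGeneticValues
    plots: pd.DataFrame


def simulate_breeding_program(config: BreedingProgramConfig,
                              arch: GeneticArchitecture) -> SimulationResult:
    """Run the whole generator: founders -> crosses/SSD -> effects -> trials."""
    config.validate()
    arch.validate(n_markers=config.n_markers)
    master = np.random.SeedSequence(config.random_seed)
    seeds = master.spawn(5)
    rng_founders = np.random.default_rng(seeds[0])
    rng_cross = np.random.default_rng(seeds[1])
    rng_effects = np.random.default_rng(seeds[2])
    rng_field = np.random.default_rng(seeds[3])
    rng_missing = np.random.default_rng(seeds[4])

    founders = simulate_founders(config, rng_founders)
    n_total = config.n_crosses * config.lines_per_cross

    if config.shared_founders:
        geno, het, cross = simulate_cross_and_ssd(
            founders, config, rng_cross, id_total=n_total)
        cross_cycle = {c: 1 + (c * config.n_cycles) // config.n_crosses
                       for c in range(config.n_crosses)}
    else:
        # Disjoint founder pools: whole crosses (hence whole families) belong
        # to a single cycle, and cycles share no ancestry.
        pools = np.array_split(np.arange(config.n_founders), config.n_cycles)
        per_cycle = config.n_crosses // config.n_cycles
        pieces, cross_cycle, offset, cross_idx = [], {}, 0, 0
        for cyc, pool in enumerate(pools, start=1):
            pairs = []
            n_here = per_cycle + (config.n_crosses % config.n_cycles if cyc == config.n_cycles else 0)
            for _ in range(n_here):
                i, j = rng_cross.choice(pool, size=2, replace=False)
                pairs.append((int(i), int(j)))
            g, h, cr = simulate_cross_and_ssd(
                founders, config, rng_cross, cross_pairs=pairs,
                id_offset=offset, id_total=n_total)
            cr = cr + cross_idx
            for c in range(cross_idx, cross_idx + n_here):
                cross_cycle[c] = cyc
            pieces.append((g, h, cr))
            offset += len(g)
            cross_idx += n_here
        geno = pd.concat([p[0] for p in pieces])
        het = pd.concat([p[1] for p in pieces])
        cross = pd.concat([p[2] for p in pieces])

    truth = assign_genetic_effects(geno, arch, rng_effects)

    # Assign lines to cycles by family; checks come from leftover lines.
    cycle_of = {}
    slots = {c: config.lines_per_cycle for c in range(1, config.n_cycles + 1)}
    leftovers = []
    for lid in geno.index:
        cyc = cross_cycle[int(cross[lid])]
        if slots.get(cyc, 0) > 0:
            cycle_of[lid] = cyc
            slots[cyc] -= 1
        else:
            leftovers.append(lid)
    unfilled = {c: k for c, k in slots.items() if k > 0}
    for cyc, k in unfilled.items():
        if config.shared_founders:
            take, leftovers = leftovers[:k], leftovers[k:]
            if len(take) < k:
                raise ConfigurationError("not enough lines to fill all cycles")
            for lid in take:
                cycle_of[lid] = cyc
        else:
            raise ConfigurationError(
                f"cycle {cyc} is short of {k} lines; increase n_crosses or lines_per_cross")
    if len(leftovers) < config.n_checks_per_block:
        raise ConfigurationError("not enough leftover lines to act as checks")
    check_ids = leftovers[:config.n_checks_per_block]

    plots = simulate_field_trials(
        geno, truth, config, arch, rng_field,
        cycle_of=pd.Series(cycle_of), check_ids=check_ids)

    observed = inject_missing(geno, config.missing_genotype_rate, rng_missing)

    line_info = pd.DataFrame({
        "cross": cross,
        "cycle": pd.Series(cycle_of).reindex(geno.index),
        "is_check": [lid in set(check_ids) for lid in geno.index],
    }, index=geno.index)
    # drop simulated lines that entered neither a cycle nor the check set
    used = line_info["cycle"].notna() | line_info["is_check"]
    line_info = line_info[used]
    geno = geno.loc[line_info.index]
    observed = observed.loc[line_info.index]
    het = het.loc[line_info.index]
    truth.values = truth.values.loc[line_info.index]

    return SimulationResult(config=config, arch=arch, founders=founders,
                            genotypes=geno, genotypes_observed=observed,
                            heterozygosity=het, line_info=line_info,
                            truth=truth, plots=plots)


def export_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write genotype / plot / truth / effects CSVs plus the config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.csv",
        "plots": outdir / "plots.csv",
        "truth": outdir / "truth.csv",
        "additive_effects": outdir / "additive_effects.csv",
        "epistatic_effects": outdir / "epistatic_effects.csv",
        "config": outdir / "config.yaml",
    }
    result.genotypes_observed.to_csv(paths["genotypes"], index_label="line_id")
    cols = ["plot_id", "line_id", "is_check", "cycle", "year", "location",
            "trial", "block", "x", "y", "yield_kg"]
    result.plots[cols].to_csv(paths["plots"], index=False)
    truth = result.truth.values.rename(columns={
        "additive": "true_additive", "epistatic": "true_epistatic", "total": "true_total"})
    truth.to_csv(paths["truth"], index_label="line_id")
    result.truth.additive_effects.to_csv(paths["additive_effects"], index_label="marker_id")
    result.truth.epistatic_effects.to_csv(paths["epistatic_effects"], index=False)
    cfg = dataclasses.asdict(result.config)
    cfg["founder_maf_distribution"] = list(cfg["founder_maf_distribution"])
    cfg["architecture"] = {
        "n_additive_qtl": result.arch.n_additive_qtl,
        "n_epistatic_pairs": result.arch.n_epistatic_pairs,
        "target_variances": dict(result.arch.target_variances),
        "effect_distribution": result.arch.effect_distribution,
    }
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
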
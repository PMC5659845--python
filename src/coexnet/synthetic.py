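"""Ground-truthed synthetic worlds for end-to-end pipeline testing.

A world is a gene universe with disjoint planted coexpression modules.
Module members share a regulation effect (a mean log2 shift, possibly
different per experiment, so clusters can be shared or unshared between
experiments) and appear in each other's coexpression partner lists with a
tunable fidelity.  From one world the generator emits every input the
pipeline reads — replicate differential-expression tables, a partner
database, companion-experiment tables with missing genes, and a
genome-wide target-class ranking with a controllable enrichment — all as
pure functions of (parameters, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coexdb import CoexpressionDatabase
from .enrichment import TargetRanking
from .expression import DifferentialExpressionTable

#: Default genome size keeps full-pipeline tests sub-second.
DEFAULT_G = 2000
#: Genome size of the paper-scale preset (a C. elegans expression array
#: samples ~27k transcripts).
PAPER_SCALE_G = 26959

_PARTNER_STREAM = 1
_TARGET_STREAM = 2
_CODING_STREAM = 3

#: Partner multiplicities are drawn uniformly from 1..MULT_MAX.
MULT_MAX = 3


@dataclass(frozen=True)
class ModuleSpec:
    """One planted coexpression module.

    ``effects`` maps experiment label -> mean log2 shift of the members in
    that experiment (absent labels mean no regulation); ``fidelity`` is the
    per-slot probability that a member's partner-list entry is another
    member rather than a random gene.

    A transcriptional program rarely ends at an arbitrary hit cutoff: genes
    coexpressed with a strongly regulated core typically respond more
    weakly, ranking just below the strongest hits.  ``halo_size`` plants
    such a fringe: halo genes share the module's coexpression pool (they
    appear in members' partner lists and vice versa) but are shifted by
    only ``halo_effect_scale`` times the core effect, so a top-n hit list
    truncates the program and leaves the halo as its natural prediction
    substrate.
    """

    name: str
    size: int
    effects: Mapping[str, float] = field(default_factory=dict)
    fidelity: float = 0.9
    halo_size: int = 0
    halo_effect_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"module {self.name!r}: size must be positive")
        if self.halo_size < 0:
            raise ValueError(f"module {self.name!r}: halo_size must be >= 0")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError(f"module {self.name!r}: fidelity must be in [0, 1]")
        for label, eff in self.effects.items():
            if not np.isfinite(eff):
                raise ValueError(f"module {self.name!r}: non-finite effect for {label!r}")


@dataclass(frozen=True)
class WorldParams:
    """Declarative description of a synthetic world."""

    G: int = DEFAULT_G
    modules: tuple[ModuleSpec, ...] = ()
    experiments: tuple[str, ...] = ("main",)
    noise_sd: float = 1.0
    n_replicates: int = 3
    K: int = 40
    #: Per-replicate multiplier on module effects (variable response strength
    #: between biological replicates); length n_replicates, default all 1.
    replicate_scale: tuple[float, ...] | None = None
    #: Per-experiment fraction of genes missing from that experiment's table.
    missing_fraction: Mapping[str, float] = field(default_factory=dict)
    #: Fraction of non-protein-coding genes in the universe.
    noncoding_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError("G must be at least 2")
        if sum(m.size + m.halo_size for m in self.modules) > self.G:
            raise ValueError("module (core + halo) sizes exceed genome size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.replicate_scale is not None and len(self.replicate_scale) != self.n_replicates:
            raise ValueError("replicate_scale length must equal n_replicates")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")


@dataclass(frozen=True)
class SyntheticWorld:
    """A realised world: gene ids, module memberships, coding flags, seed."""

    params: WorldParams
    seed: int
    genes: tuple[str, ...]
    module_members: Mapping[str, tuple[str, ...]]
    module_halos: Mapping[str, tuple[str, ...]]
    coding: Mapping[str, bool]

    def members(self, module: str) -> tuple[str, ...]:
        """Core members of a module (the strongly regulated genes)."""
        return self.module_members[module]

    def halo(self, module: str) -> tuple[str, ...]:
        """Weakly regulated coexpressed fringe of a module."""
        return self.module_halos[module]

    @property
    def truth(self) -> dict:
        """Full ground-truth record (memberships, effects, generator knobs)."""
        return {
            "seed": self.seed,
            "G": self.params.G,
            "K": self.params.K,
            "noise_sd": self.params.noise_sd,
            "n_replicates": self.params.n_replicates,
            "experiments": list(self.params.experiments),
            "multiplicity_distribution": f"uniform integers 1..{MULT_MAX}",
            "modules": {
                m.name: {
                    "members": list(self.module_members[m.name]),
                    "halo": list(self.module_halos[m.name]),
                    "effects": dict(m.effects),
                    "fidelity": m.fidelity,
                    "halo_effect_scale": m.halo_effect_scale,
                }
                for m in self.params.modules
            },
        }


def _stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _label_stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, 10, zlib.crc32(label.encode())])


def generate_world(params: WorldParams, seed: int) -> SyntheticWorld:
    """Realise a world: deterministic gene ids and module memberships."""
    width = len(str(params.G - 1))
    genes = tuple(f"g{i:0{width}d}" for i in range(params.G))
    rng = _stream(seed, 0)
    order = rng.permutation(params.G)
    members: dict[str, tuple[str, ...]] = {}
    halos: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for mod in params.modules:
        idx = order[cursor : cursor + mod.size]
        members[mod.name] = tuple(sorted(genes[i] for i in idx))
        cursor += mod.size
        hidx = order[cursor : cursor + mod.halo_size]
        halos[mod.name] = tuple(sorted(genes[i] for i in hidx))
        cursor += mod.halo_size
    coding_rng = _stream(seed, _CODING_STREAM)
    coding_flags = coding_rng.random(params.G) >= params.noncoding_fraction
    coding = {g: bool(c) for g, c in zip(genes, coding_flags)}
    return SyntheticWorld(
        params=params,
        seed=seed,
        genes=genes,
        module_members=members,
        module_halos=halos,
        coding=coding,
    )


def _sample_distinct(rng: np.random.Generator, n_pool: int, k: int, forbid: set[int]) -> list[int]:
    """k distinct indices from range(n_pool) avoiding ``forbid``; oversamples
    with replacement and deduplicates (cheap for k << n_pool)."""
    out: list[int] = []
    seen = set(forbid)
    while len(out) < k:
        draw = rng.integers(0, n_pool, size=2 * (k - len(out)) + 4)
        for idx in draw:
            idx = int(idx)
            if idx not in seen:
                seen.add(idx)
                out.append(idx)
                if len(out) == k:
                    break
    return out


def emit_partner_db(world: SyntheticWorld) -> CoexpressionDatabase:
    """Partner database consistent with the planted modules.

    A member's K slots hold co-members with probability ``fidelity`` each
    (sampled without replacement, random fillers once co-members are
    exhausted); every other slot and every non-member gene gets uniform
    random distinct partners.  A module's coexpression pool is its core
    plus its halo: both list each other.  Multiplicities are uniform on
    1..3.
    """
    params = world.params
    rng = _stream(world.seed, _PARTNER_STREAM)
    genes = world.genes
    index = {g: i for i, g in enumerate(genes)}
    pool_of: dict[str, tuple[str, ...]] = {}
    fidelity_of: dict[str, float] = {}
    for mod in params.modules:
        pool = tuple(sorted(world.module_members[mod.name] + world.module_halos[mod.name]))
        for g in pool:
            pool_of[g] = pool
            fidelity_of[g] = mod.fidelity

    partner_lists: dict[str, tuple[tuple[str, int], ...]] = {}
    for gi, gene in enumerate(genes):
        k = min(params.K, params.G - 1)
        pool = pool_of.get(gene)
        if pool is None:
            chosen = _sample_distinct(rng, params.G, k, {gi})
            partners = [genes[i] for i in chosen]
        else:
            co = [g for g in pool if g != gene]
            n_co_slots = int(rng.binomial(k, fidelity_of[gene]))
            n_co = min(n_co_slots, len(co))
            co_pick = (
                list(rng.choice(np.array(co), size=n_co, replace=False)) if n_co else []
            )
            forbid = {gi} | {index[c] for c in co_pick}
            filler = [genes[i] for i in _sample_distinct(rng, params.G, k - n_co, forbid)]
            slots = np.zeros(k, dtype=bool)
            if n_co:
                slots[rng.choice(k, size=n_co, replace=False)] = True
            partners = []
            ci = fi = 0
            for is_co in slots:
                if is_co:
                    partners.append(str(co_pick[ci]))
                    ci += 1
                else:
                    partners.append(filler[fi])
                    fi += 1
        mults = rng.integers(1, MULT_MAX + 1, size=k)
        partner_lists[gene] = tuple((p, int(c)) for p, c in zip(partners, mults))
    return CoexpressionDatabase(K=params.K, partner_lists=partner_lists)


def emit_expression(world: SyntheticWorld, experiment: str) -> DifferentialExpressionTable:
    """Replicate log2 differential-expression table for one experiment.

    Each replicate value is the gene's planted effect in this experiment
    (0 for genes outside every module) scaled by the replicate's response
    strength, plus Gaussian noise.  Genes drawn by the experiment's missing
    fraction get all-NA rows (they were "not tested").
    """
    params = world.params
    if experiment not in params.experiments:
        raise ValueError(f"unknown experiment label {experiment!r}")
    rng = _label_stream(world.seed, experiment)
    effects = np.zeros(params.G)
    index = {g: i for i, g in enumerate(world.genes)}
    for mod in params.modules:
        eff = mod.effects.get(experiment, 0.0)
        if eff:
            for g in world.module_members[mod.name]:
                effects[index[g]] = eff
            for g in world.module_halos[mod.name]:
                effects[index[g]] = eff * mod.halo_effect_scale
    scale = np.asarray(params.replicate_scale or [1.0] * params.n_replicates)
    values = effects[:, None] * scale[None, :] + rng.normal(
        0.0, params.noise_sd, size=(params.G, params.n_replicates)
    )
    frac = float(params.missing_fraction.get(experiment, 0.0))
    if frac > 0:
        missing = rng.random(params.G) < frac
        values[missing, :] = np.nan
    df = pd.DataFrame(
        values,
        index=pd.Index(world.genes, name="gene"),
        columns=[f"rep{r + 1}" for r in range(params.n_replicates)],
    )
    coding = pd.Series([world.coding[g] for g in world.genes], index=df.index)
    return DifferentialExpressionTable(values=df, coding=coding)


def emit_target_ranking(
    world: SyntheticWorld,
    n_class1: int,
    n_class2: int,
    enriched_module: str | None = None,
    strength: float = 0.0,
) -> TargetRanking:
    """Genome-wide target ranking with a controllable planted enrichment.

    A fraction ``strength`` of the enriched module's members is placed
    uniformly inside the Class I block; every other gene is placed
    uniformly over the remaining positions.
    """
    params = world.params
    if n_class1 < 0 or n_class2 < 0 or n_class1 + n_class2 > params.G:
        raise ValueError("class sizes must be non-negative and fit the genome")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = _stream(world.seed, _TARGET_STREAM)
    order = np.empty(params.G, dtype=object)
    placed: set[str] = set()
    filled = np.zeros(params.G, dtype=bool)
    if enriched_module is not None and strength > 0:
        members = np.array(world.members(enriched_module))
        n_in = int(round(strength * len(members)))
        chosen = rng.choice(members, size=n_in, replace=False) if n_in else members[:0]
        slots = rng.choice(n_class1, size=len(chosen), replace=False)
        for gene, slot in zip(chosen, slots):
            order[slot] = str(gene)
            filled[slot] = True
            placed.add(str(gene))
    rest = np.array([g for g in world.genes if g not in placed])
    rng.shuffle(rest)
    order[~filled] = rest
    return TargetRanking(
        ordered_genes=tuple(order.tolist()), n_class1=n_class1, n_class2=n_class2
    )


# ---------------------------------------------------------------------------
# presets and YAML config
# ---------------------------------------------------------------------------

def default_world_params() -> WorldParams:
    """Small world for fast tests: 2000 genes, two upregulated modules (one
    shared with a companion experiment, one not; each with a weakly
    regulated coexpressed halo) and one downregulated module, three
    replicates, effect-to-noise ratio 3."""
    return WorldParams(
        G=DEFAULT_G,
        modules=(
            ModuleSpec(
                "up_shared", 60, {"main": 3.0, "companion": 3.0}, fidelity=0.9, halo_size=50
            ),
            ModuleSpec("up_private", 60, {"main": 3.0}, fidelity=0.9, halo_size=50),
            ModuleSpec("down_private", 60, {"main": -3.0}, fidelity=0.9, halo_size=50),
        ),
        experiments=("main", "companion"),
        noise_sd=1.0,
        n_replicates=3,
        K=40,
        missing_fraction={"companion": 0.05},
    )


def paper_scale_params() -> WorldParams:
    """Paper-scale world: ~27k-transcript genome, a planted 60-gene
    upregulated module (effect +3, noise 1, fidelity 0.9) with a 100-gene
    half-effect coexpressed halo, 250-gene hit lists, K=40 partner lists."""
    return WorldParams(
        G=PAPER_SCALE_G,
        modules=(ModuleSpec("up_module", 60, {"main": 3.0}, fidelity=0.9, halo_size=100),),
        experiments=("main",),
        noise_sd=1.0,
        n_replicates=3,
        K=40,
    )


def load_world_config(path: str | Path) -> WorldParams:
    """Read a WorldParams from YAML (keys mirror the dataclass fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    modules = tuple(
        ModuleSpec(
            name=m["name"],
            size=int(m["size"]),
            effects={str(k): float(v) for k, v in (m.get("effects") or {}).items()},
            fidelity=float(m.get("fidelity", 0.9)),
            halo_size=int(m.get("halo_size", 0)),
            halo_effect_scale=float(m.get("halo_effect_scale", 0.5)),
        )
        for m in cfg.get("modules", [])
    )
    return WorldParams(
        G=int(cfg.get("G", DEFAULT_G)),
        modules=modules,
        experiments=tuple(cfg.get("experiments", ["main"])),
        noise_sd=float(cfg.get("noise_sd", 1.0)),
        n_replicates=int(cfg.get("n_replicates", 3)),
        K=int(cfg.get("K", 40)),
        replicate_scale=(
            tuple(float(x) for x in cfg["replicate_scale"])
            if cfg.get("replicate_scale")
            else None
        ),
        missing_fraction={str(k): float(v) for k, v in (cfg.get("missing_fraction") or {}).items()},
        noncoding_fraction=float(cfg.get("noncoding_fraction", 0.0)),
    )
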
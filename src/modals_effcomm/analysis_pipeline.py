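"""End-to-end experiment: generate, measure, evolve, score, summarize.

The pipeline samples a pool of hypothetical modal inventories, optionally
adds attested-style inventories (read from a judgment table or produced by
the naturalistic generator), estimates the Pareto frontier of the
complexity/cost trade-off, scores every language for optimality and
naturalness, and computes the headline statistics: Pearson correlations of
naturalness with simplicity, informativeness and optimality, and one-sided
t-tests comparing the natural-style subset against the population mean.

For reporting, *simplicity* is 1 minus min-max-normalized complexity and
*informativeness* is 1 minus (normalized) cost, so all summary quantities
live on the same [0, 1] scale as optimality.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .communication_measures import AgentConfig, communicative_cost, ib_cost
from .lot_complexity import complexity_table, language_complexity, vocabulary_entropy, vocabulary_size
from .meaning_space import MeaningSpace, build_space, estimated_need, load_need, uniform_need
from .pareto_optimization import (
    EvolutionConfig,
    MeasuredLanguage,
    evolve,
    four_corner_exploration,
    normalization_ranges,
    score_optimality,
)
from .synthetic_data import SamplerConfig, generate_naturalistic_inventories, generate_pool
from .typology_io import Language, read_inventories, remove_synonyms

__all__ = [
    "DEFAULT_CONFIG",
    "LanguageMeasurer",
    "ExperimentResult",
    "load_config",
    "make_need",
    "run_experiment",
    "naturalness_correlations",
    "group_comparison",
    "condition_grid",
    "run_conditions",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "space": {"forces": ["weak", "strong"], "flavors": ["epistemic", "deontic", "circumstantial"]},
    "sampling": {"max_size": 10, "n_per_cell": 100},
    "naturalistic": {"n": 27, "synonymy_rate": 0.15},
    "inventories": None,
    "complexity": {"measure": "mdl", "max_atoms": None},
    "informativeness": {
        "agents": "literal",
        "utility": "graded",
        "prior": "estimated",
        "alpha": 1.0,
        "measure": "expected_utility",
        "similarity_scale": 1.0,
    },
    "evolution": {"population": 2000, "generations": 200, "max_mutations": 5},
    "analysis": {"metric": "euclidean", "four_corners": False, "remove_synonyms": False},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a run configuration: defaults <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def make_need(space: MeaningSpace, prior: str):
    """Resolve the need-distribution config knob: uniform | estimated | path."""
    if prior == "uniform":
        return uniform_need(space)
    if prior == "estimated":
        return estimated_need(space)
    return load_need(prior, space)


class LanguageMeasurer:
    """Maps a language to its (complexity, cost) trade-off coordinates.

    Complexity: ``mdl`` (sum of shortest-formula lengths), ``size``
    (vocabulary size), or ``entropy`` (vocabulary entropy in bits under the
    literal speaker).  Cost: ``expected_utility`` (1 - I(L) for the chosen
    agents/utility) or ``ib`` (Information Bottleneck cost in bits).
    Results are cached per multiset of meanings.
    """

    def __init__(
        self,
        space: MeaningSpace,
        need,
        complexity_measure: str = "mdl",
        cost_measure: str = "expected_utility",
        agents: AgentConfig = AgentConfig(),
        max_atoms: int | None = None,
        similarity_scale: float = 1.0,
    ):
        if complexity_measure not in ("mdl", "size", "entropy"):
            raise ValueError(f"unknown complexity measure {complexity_measure!r}")
        if cost_measure not in ("expected_utility", "ib"):
            raise ValueError(f"unknown cost measure {cost_measure!r}")
        self.space = space
        self.need = need
        self.complexity_measure = complexity_measure
        self.cost_measure = cost_measure
        self.agents = agents
        self.similarity_scale = similarity_scale
        self.table = complexity_table(space, max_atoms) if complexity_measure == "mdl" else None
        self._cache: dict[tuple, tuple[float, float]] = {}

    @property
    def cost_in_bits(self) -> bool:
        return self.cost_measure == "ib"

    def complexity(self, L: Language) -> float:
        if self.complexity_measure == "mdl":
            return float(language_complexity(L, self.table))
        if self.complexity_measure == "size":
            return float(vocabulary_size(L))
        return vocabulary_entropy(L, self.need)

    def cost(self, L: Language) -> float:
        if self.cost_measure == "expected_utility":
            return communicative_cost(L, self.need, self.agents)
        return ib_cost(L, self.need, self.similarity_scale)

    def __call__(self, L: Language) -> tuple[float, float]:
        key = L.canonical_key()
        hit = self._cache.get(key)
        if hit is None:
            hit = (self.complexity(L), self.cost(L))
            self._cache[key] = hit
        return hit


@dataclass
class ExperimentResult:
    pool: pd.DataFrame
    frontier: pd.DataFrame
    correlations: pd.DataFrame
    comparison: pd.DataFrame
    config: dict


def _measured_frame(measured: list[MeasuredLanguage], ranges) -> pd.DataFrame:
    (clo, chi), (klo, khi) = ranges
    rows = []
    for m in measured:
        norm_comp = (m.complexity - clo) / (chi - clo) if chi > clo else 0.0
        norm_cost = (m.cost - klo) / (khi - klo) if khi > klo else m.cost
        rows.append(
            {
                "name": m.language.name,
                "provenance": m.language.provenance,
                "size": m.language.size,
                "complexity": m.complexity,
                "cost": m.cost,
                "simplicity": 1.0 - norm_comp,
                "informativeness": 1.0 - norm_cost,
                "naturalness": m.naturalness,
                "optimality": m.optimality,
            }
        )
    return pd.DataFrame(rows)


def naturalness_correlations(pool: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p, N) of naturalness with each reported property.

    Degenerate (constant) columns yield NaN with a note rather than an
    error, matching how an undefined correlation should be surfaced.
    """
    rows = []
    y = pool["naturalness"].to_numpy(float)
    for prop in ("simplicity", "informativeness", "optimality"):
        x = pool[prop].to_numpy(float)
        n = len(x)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"property": prop, "r": np.nan, "p": np.nan, "n": n, "note": "undefined (constant column or n < 3)"})
            continue
        r, p = stats.pearsonr(y, x)
        rows.append({"property": prop, "r": float(r), "p": float(p), "n": n, "note": ""})
    return pd.DataFrame(rows)


def group_comparison(pool: pd.DataFrame, natural_mask) -> pd.DataFrame:
    """Mean simplicity/informativeness/optimality for the natural-style
    subset vs. the whole population, with one-sided one-sample t-tests of
    the subset scoring above the population mean."""
    natural_mask = np.asarray(natural_mask, bool)
    if not natural_mask.any():
        raise ValueError("empty natural subset")
    rows = []
    for prop in ("simplicity", "informativeness", "optimality"):
        vals = pool[prop].to_numpy(float)
        sub = vals[natural_mask]
        pop_mean = float(np.mean(vals))
        row = {
            "property": prop,
            "n_natural": int(natural_mask.sum()),
            "n_population": len(vals),
            "natural_mean": float(np.mean(sub)),
            "population_mean": pop_mean,
            "difference": float(np.mean(sub) - pop_mean),
        }
        if len(sub) >= 2 and np.std(sub) > 0:
            t, p = stats.ttest_1samp(sub, pop_mean, alternative="greater")
            row["t"] = float(t)
            row["p"] = float(p)
        else:
            row["t"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Display rule for vanishing p-values."""
    if np.isnan(p):
        return "nan"
    return "~0" if p < 1e-10 else f"{p:.3g}"


def run_experiment(config: dict | None = None, outdir=None, seed: int | None = None) -> ExperimentResult:
    """Execute the full pipeline under one root seed and optionally write
    pool/frontier/summary CSVs plus the resolved configuration."""
    cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    root = np.random.SeedSequence(cfg["seed"])
    s_sample, s_nat, s_evol, s_init = (int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(4))

    space = build_space(cfg["space"]["forces"], cfg["space"]["flavors"])
    need = make_need(space, cfg["informativeness"]["prior"])
    agents = AgentConfig(
        agent_kind=cfg["informativeness"]["agents"],
        utility_kind=cfg["informativeness"]["utility"],
        alpha=float(cfg["informativeness"]["alpha"]),
    )
    cost_measure = "ib" if cfg["informativeness"]["measure"] == "ib" else "expected_utility"
    measurer = LanguageMeasurer(
        space,
        need,
        complexity_measure=cfg["complexity"]["measure"],
        cost_measure=cost_measure,
        agents=agents,
        max_atoms=cfg["complexity"]["max_atoms"],
        similarity_scale=float(cfg["informativeness"]["similarity_scale"]),
    )

    # 1. assemble languages: stratified sample + natural(-style) inventories
    sampler = SamplerConfig(
        max_size=int(cfg["sampling"]["max_size"]),
        n_per_cell=int(cfg["sampling"]["n_per_cell"]),
        seed=s_sample,
    )
    sampled = generate_pool(space, sampler)
    logger.info("stage=sample n=%d", len(sampled))

    natural: list[Language] = []
    if cfg["inventories"]:
        natural = read_inventories(cfg["inventories"], space)
    elif cfg["naturalistic"]["n"]:
        natural = generate_naturalistic_inventories(
            space,
            int(cfg["naturalistic"]["n"]),
            np.random.default_rng(s_nat),
            synonymy_rate=float(cfg["naturalistic"]["synonymy_rate"]),
        )
    if cfg["analysis"]["remove_synonyms"]:
        natural = [remove_synonyms(L) for L in natural]
    logger.info("stage=natural n=%d", len(natural))

    # 2. evolutionary frontier estimation (minimize both), seeded from the sample
    evo = EvolutionConfig(
        population=int(cfg["evolution"]["population"]),
        generations=int(cfg["evolution"]["generations"]),
        max_mutations=int(cfg["evolution"]["max_mutations"]),
        seed=s_evol,
    )
    init_rng = np.random.default_rng(s_init)
    if len(sampled) > evo.population:
        idx = init_rng.choice(len(sampled), size=evo.population, replace=False)
        initial = [sampled[i] for i in sorted(idx)]
    else:
        initial = list(sampled)
    frontier, explored = evolve(initial, measurer, space, evo)
    logger.info("stage=evolve frontier=%d explored=%d", len(frontier), len(explored))

    extra_explored: list[MeasuredLanguage] = []
    if cfg["analysis"]["four_corners"]:
        _, union = four_corner_exploration(initial, measurer, space, evo)
        extra_explored = union

    # 3. measure the pooled unique languages and score optimality
    pool_map: dict[tuple, MeasuredLanguage] = {}
    from .universals import naturalness as _nat

    def add(L: Language) -> None:
        key = L.canonical_key()
        if key not in pool_map:
            comp, cost = measurer(L)
            pool_map[key] = MeasuredLanguage(L, comp, cost, _nat(L))

    for m in explored + extra_explored:
        pool_map.setdefault(m.language.canonical_key(), m)
    for L in sampled + natural:
        add(L)
    # natural inventories must keep their identity even if a sampled twin exists
    for L in natural:
        key = L.canonical_key()
        if pool_map[key].language.provenance != L.provenance:
            comp, cost = measurer(L)
            pool_map[key] = MeasuredLanguage(L, comp, cost, _nat(L))
    pool = list(pool_map.values())
    score_optimality(pool, frontier, metric=cfg["analysis"]["metric"], normalize_cost=measurer.cost_in_bits)
    ranges = normalization_ranges(pool + frontier, normalize_cost=measurer.cost_in_bits)
    pool_df = _measured_frame(pool, ranges).sort_values(["complexity", "cost", "name"], kind="mergesort").reset_index(drop=True)
    frontier_df = _measured_frame(frontier, ranges)

    correlations = naturalness_correlations(pool_df)
    natural_mask = pool_df["provenance"].isin(["natural", "synthetic"]).to_numpy()
    comparison = (
        group_comparison(pool_df, natural_mask) if natural_mask.any() else pd.DataFrame()
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pool_df.to_csv(outdir / "pool.csv", index=False)
        frontier_df.to_csv(outdir / "frontier.csv", index=False)
        correlations.to_csv(outdir / "summary.csv", index=False)
        comparison.to_csv(outdir / "comparison.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)

    return ExperimentResult(pool_df, frontier_df, correlations, comparison, cfg)


def condition_grid() -> list[dict]:
    """The robustness-condition matrix.

    Eight expected-utility conditions (2 priors x 2 agent kinds x 2
    utilities) plus six formalization conditions ({expected-utility, IB}
    informativeness x {mdl, entropy, size} complexity, estimated prior).
    """
    out = []
    for prior in ("estimated", "uniform"):
        for agents in ("literal", "pragmatic"):
            for utility in ("graded", "binary"):
                out.append(
                    {
                        "name": f"eu-{prior}-{agents}-{utility}",
                        "informativeness": {
                            "prior": prior,
                            "agents": agents,
                            "utility": utility,
                            "measure": "expected_utility",
                        },
                        "complexity": {"measure": "mdl"},
                    }
                )
    for inf_measure in ("expected_utility", "ib"):
        for comp in ("mdl", "entropy", "size"):
            out.append(
                {
                    "name": f"{'orig' if inf_measure == 'expected_utility' else 'ib'}-{comp}",
                    "informativeness": {
                        "prior": "estimated",
                        "agents": "literal",
                        "utility": "graded",
                        "measure": inf_measure,
                    },
                    "complexity": {"measure": comp},
                }
            )
    return out


def run_conditions(base_config: dict | None = None, outdir=None, seed: int | None = None) -> pd.DataFrame:
    """Run every robustness condition and emit one summary row per condition."""
    rows = []
    for cond in condition_grid():
        cfg = _deep_merge(base_config or {}, {k: v for k, v in cond.items() if k != "name"})
        res = run_experiment(cfg, seed=seed)
        front_nat = res.frontier["naturalness"]
        row = {
            "condition": cond["name"],
            "prior": cond["informativeness"]["prior"],
            "agents": cond["informativeness"]["agents"],
            "utility": cond["informativeness"]["utility"],
            "inf_measure": cond["informativeness"]["measure"],
            "complexity_measure": cond["complexity"]["measure"],
            "n_pool": len(res.pool),
            "n_frontier": len(res.frontier),
            "frontier_naturalness_mean": float(front_nat.mean()),
            "frontier_all_natural": bool((front_nat == 1.0).all()),
        }
        for _, r in res.correlations.iterrows():
            row[f"r_{r['property']}"] = r["r"]
        if len(res.comparison):
            for _, r in res.comparison.iterrows():
                row[f"nat_minus_pop_{r['property']}"] = r["difference"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "conditions.csv", index=False)
    return df
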
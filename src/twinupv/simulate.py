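"""Synthetic twin cohorts and mouse-colony phenotype tables.

The generator plants the statistical structure the downstream analysis
assumes and records ground-truth labels so every stage can be tested as a
recovery problem:

* Monozygotic pairs fall into four discordance groups -- ``concordant``
  (no systematic co-twin difference), ``typeA`` (heavier co-twin has more
  fat mass, slightly less lean mass), ``typeB`` (heavier co-twin has more
  fat *and* lean mass, a relative overgrowth) and ``intermediate`` (a
  half-scale Type-B pattern).  Dizygotic pairs carry no group effect but
  inflated discordance variance.
* Expression carries a Type-B-specific signature: a set of genes shifted
  in heavy Type-B co-twins (a configurable fraction down-regulated,
  housing the NNAT-like buffer gene), an HDAC-responsive set up-regulated
  in the same individuals, and a four-level population structure over the
  signature genes (light-like, neutral, mildly heavy-like, heavy-like)
  mirroring the strata the cohort stratification is meant to find.
* Serum insulin is linearly coupled to BMI with a group-specific target
  R-squared, tight only in the Type-B group.

All randomness flows from one root seed through fixed per-stream child
seeds, so e.g. changing the gene count does not perturb the trait draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .errors import ConfigurationError

GROUPS = ("concordant", "typeA", "typeB", "intermediate")

_REGIONS = (
    "head",
    "trunk",
    "arm_left",
    "arm_right",
    "leg_left",
    "leg_right",
    "android",
    "gynoid",
)

#: Rough shares of total fat / lean / body mass per region (do not need to
#: sum to one; traits are generated quasi-independently).
_REGION_SHARE = {
    "head": 0.03,
    "trunk": 0.50,
    "arm_left": 0.06,
    "arm_right": 0.06,
    "leg_left": 0.15,
    "leg_right": 0.15,
    "android": 0.08,
    "gynoid": 0.16,
}

MORPH_NAMES = ("light", "heavy", "obese")


def default_trait_panel() -> list[str]:
    """The default 35-trait morphometric panel."""
    traits: list[str] = []
    for r in _REGIONS:
        traits.append(f"fat_mass_{r}")
    for r in _REGIONS:
        traits.append(f"lean_mass_{r}")
    for r in _REGIONS:
        traits.append(f"mass_{r}")
    traits += [
        "fat_mass_total",
        "lean_mass_total",
        "fat_pct_total",
        "lean_pct_total",
        "bmc_total",
        "bmc_spine",
        "bmc_limbs",
        "weight",
        "height",
        "bmi",
        "insulin",
    ]
    return traits


def default_trait_tags(trait_names=None) -> tuple[list[str], list[str]]:
    """(fat_traits, lean_traits) tags for a trait panel."""
    names = list(trait_names) if trait_names is not None else default_trait_panel()
    fat = [t for t in names if t.startswith("fat_")]
    lean = [t for t in names if t.startswith("lean_")]
    return fat, lean


@dataclass
class SimulationConfig:
    """Parameters of the synthetic twin-cohort generator.

    Effects are log-scale mean discordances (dimensionless); expression
    effects are on the log2 scale of the array intensities.
    """

    n_pairs_per_group: dict = field(
        default_factory=lambda: {g: 40 for g in GROUPS}
    )
    n_dz_pairs: int = 40
    trait_names: list[str] = field(default_factory=default_trait_panel)
    effect_fat: float = 0.35
    effect_lean: float = 0.18
    noise_sd_traits: float = 0.08
    height_noise_sd: float = 0.01
    dz_inflation: float = 2.0
    n_genes: int = 2000
    n_signature_genes: int = 60
    frac_signature_down: float = 0.25
    hdac_set_size: int = 40
    expr_effect: float = 1.0
    expr_noise_sd: float = 0.25
    insulin_bmi_r2: dict = field(
        default_factory=lambda: {
            "concordant": 0.10,
            "typeA": 0.10,
            "typeB": 0.50,
            "intermediate": 0.10,
            "dz": 0.10,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if g not in self.n_pairs_per_group:
                raise ConfigurationError(f"n_pairs_per_group missing group {g!r}")
            if int(self.n_pairs_per_group[g]) < 0:
                raise ConfigurationError(f"n_pairs_per_group[{g!r}] must be >= 0")
        if sum(int(v) for v in self.n_pairs_per_group.values()) <= 0:
            raise ConfigurationError("n_pairs_per_group: at least one pair required")
        if self.n_dz_pairs < 0:
            raise ConfigurationError("n_dz_pairs must be >= 0")
        if "bmi" not in self.trait_names or "height" not in self.trait_names:
            raise ConfigurationError("trait_names must contain 'bmi' and 'height'")
        fat, lean = default_trait_tags(self.trait_names)
        if not fat or not lean:
            raise ConfigurationError(
                "trait_names must contain at least one fat_ and one lean_ trait"
            )
        if self.noise_sd_traits <= 0:
            raise ConfigurationError("noise_sd_traits must be > 0")
        if self.expr_noise_sd <= 0:
            raise ConfigurationError("expr_noise_sd must be > 0")
        if not (0.0 <= self.frac_signature_down <= 1.0):
            raise ConfigurationError("frac_signature_down must be in [0, 1]")
        for k, v in self.insulin_bmi_r2.items():
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigurationError(f"insulin_bmi_r2[{k!r}] must be in [0, 1]")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be > 0")
        if self.n_signature_genes + self.hdac_set_size > self.n_genes:
            raise ConfigurationError(
                "n_signature_genes + hdac_set_size must not exceed n_genes"
            )


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    """Child generator for a fixed stream index under the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg_seed, spawn_key=(stream,))
    )


def _group_effect(trait: str, group: str, cfg: SimulationConfig) -> float:
    """Planted mean log-discordance for one trait in one pair group."""
    if group in ("concordant", "dz"):
        return 0.0
    scale = 0.5 if group == "intermediate" else 1.0
    f = cfg.effect_fat * scale
    lean_sign = -1.0 if group == "typeA" else 1.0
    le = lean_sign * cfg.effect_lean * scale
    if trait.startswith("fat_"):
        return f
    if trait.startswith("lean_"):
        return le
    if trait.startswith("bmc_"):
        return 0.5 * le
    if trait == "weight" or trait.startswith("mass_"):
        # composite of fat and lean, floored so the planted heavy co-twin
        # stays the heavier one by body mass even in Type-A pairs
        return max(0.3 * f + 0.7 * le, 0.25 * f)
    return 0.0


def _mz_marginal_sd(trait: str, cfg: SimulationConfig, noise_sd: float) -> float:
    """Marginal s.d. of an MZ trait discordance across the planted groups.

    The MZ discordance distribution is a mixture over groups of
    N(effect_g, noise_sd^2); DZ discordance noise is scaled to
    ``dz_inflation`` times this marginal s.d. so dizygotic pairs are more
    discordant than monozygotic ones for every trait, effects included.
    """
    counts = np.array([max(int(cfg.n_pairs_per_group[g]), 0) for g in GROUPS], float)
    if counts.sum() == 0:
        return noise_sd
    w = counts / counts.sum()
    effects = np.array([_group_effect(trait, g, cfg) for g in GROUPS])
    var_eff = float(w @ effects**2 - (w @ effects) ** 2)
    return math.sqrt(var_eff + noise_sd**2)


def _baseline_logmean(trait: str) -> float:
    if trait.startswith("fat_mass_"):
        region = trait[len("fat_mass_"):]
        return math.log(22.0 * _REGION_SHARE.get(region, 1.0))
    if trait.startswith("lean_mass_"):
        region = trait[len("lean_mass_"):]
        return math.log(42.0 * _REGION_SHARE.get(region, 1.0))
    if trait.startswith("mass_"):
        region = trait[len("mass_"):]
        return math.log(66.0 * _REGION_SHARE.get(region, 1.0))
    if trait.startswith("bmc_"):
        return math.log(2.5)
    if trait == "fat_pct_total":
        return math.log(33.0)
    if trait == "lean_pct_total":
        return math.log(62.0)
    return math.log(10.0)


def simulate_twin_cohort(cfg: SimulationConfig) -> TwinCohort:
    """Generate phenotypes for MZ pairs in four planted groups plus DZ pairs.

    The lighter co-twin's traits are drawn from a log-normal baseline; the
    heavier one multiplies them by ``exp(group effect + noise)``.  BMI is
    derived as weight / height^2; insulin is coupled to BMI per group.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 0)
    sampled = [
        t for t in cfg.trait_names if t not in ("bmi", "insulin", "weight", "height")
    ]

    rows = []
    pair_group: dict[str, str] = {}
    morph: dict[str, str] = {}
    pair_idx = 0
    plan = [(g, int(cfg.n_pairs_per_group[g]), "MZ") for g in GROUPS]
    plan.append(("dz", int(cfg.n_dz_pairs), "DZ"))
    for group, n_pairs, zyg in plan:
        for _ in range(n_pairs):
            pair_idx += 1
            pair = f"P{pair_idx:04d}"
            light_id, heavy_id = f"{pair}a", f"{pair}b"
            pair_group[pair] = group
            morph[light_id] = "light"
            morph[heavy_id] = "heavy"
            sex = "F" if rng.random() < 0.8 else "M"
            age = int(rng.integers(40, 80))
            sex_shift = 0.0 if sex == "F" else 0.12
            is_dz = group == "dz"
            noise_sd = cfg.noise_sd_traits
            height_sd = cfg.height_noise_sd * (cfg.dz_inflation if is_dz else 1.0)

            height_l = math.exp(0.482 + sex_shift * 0.5 + rng.normal(0.0, 0.035))
            height_h = height_l * math.exp(rng.normal(0.0, height_sd))
            weight_sd = (
                cfg.dz_inflation * _mz_marginal_sd("weight", cfg, noise_sd / 2.0)
                if is_dz
                else noise_sd / 2.0
            )
            weight_l = math.exp(4.17 + sex_shift + rng.normal(0.0, 0.15))
            weight_h = weight_l * math.exp(
                _group_effect("weight", group, cfg) + rng.normal(0.0, weight_sd)
            )
            rec_l = {"pair": pair, "zygosity": zyg, "sex": sex, "age": age}
            rec_h = dict(rec_l)
            rec_l["weight"], rec_h["weight"] = weight_l, weight_h
            rec_l["height"], rec_h["height"] = height_l, height_h
            rec_l["bmi"] = weight_l / height_l**2
            rec_h["bmi"] = weight_h / height_h**2
            for t in sampled:
                base = math.exp(
                    _baseline_logmean(t) + sex_shift + rng.normal(0.0, 0.2)
                )
                t_sd = (
                    cfg.dz_inflation * _mz_marginal_sd(t, cfg, noise_sd)
                    if is_dz
                    else noise_sd
                )
                rec_l[t] = base
                rec_h[t] = base * math.exp(
                    _group_effect(t, group, cfg) + rng.normal(0.0, t_sd)
                )
            rows.append(pd.Series(rec_l, name=light_id))
            rows.append(pd.Series(rec_h, name=heavy_id))

    pheno = pd.DataFrame(rows)
    pheno.index.name = "individual"
    _add_insulin(cfg, pheno, pair_group)
    ordered = ["pair", "zygosity", "sex", "age"] + list(cfg.trait_names)
    pheno = pheno[[c for c in ordered if c in pheno.columns]]
    truth = {"pair_group": pair_group, "morph": morph}
    cohort = TwinCohort(pheno, None, list(cfg.trait_names), truth)
    cohort.validate()
    return cohort


def _add_insulin(cfg: SimulationConfig, pheno: pd.DataFrame, pair_group) -> None:
    """Insulin = a*BMI + noise, noise variance solved from the target R^2.

    R^2 = a^2 var(BMI) / (a^2 var(BMI) + sigma^2)  =>
    sigma^2 = a^2 var(BMI) (1 - R^2) / R^2, with a = 1 and an offset chosen
    to keep insulin positive (arbitrary units).
    """
    rng = _rng(cfg.seed, 1)
    group_of = pheno["pair"].map(pair_group)
    insulin = pd.Series(np.nan, index=pheno.index)
    for group in list(GROUPS) + ["dz"]:
        mask = (group_of == group).to_numpy()
        if mask.sum() == 0:
            continue
        bmi = pheno.loc[mask, "bmi"].to_numpy(dtype=float)
        r2 = float(cfg.insulin_bmi_r2.get(group, 0.0))
        if r2 <= 0.0:
            vals = 30.0 + rng.normal(0.0, 5.0, size=mask.sum())
        else:
            a = 1.0
            sigma = math.sqrt(a**2 * np.var(bmi) * (1.0 - r2) / r2)
            vals = 10.0 + a * bmi + rng.normal(0.0, sigma, size=mask.sum())
        insulin.loc[mask] = np.clip(vals, 0.1, None)
    pheno["insulin"] = insulin


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gene_names(n_genes: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n_genes + 1)]


def simulate_expression(cfg: SimulationConfig, cohort: TwinCohort) -> TwinCohort:
    """Fill the cohort's expression matrix with the planted signature.

    Null genes are i.i.d. noise around gene-specific baselines.  Signature
    genes are shifted +/- ``expr_effect`` in heavy Type-B co-twins (with the
    opposite shift in their light co-twins, and a shared half-scale shift in
    both co-twins of intermediate pairs, creating the four population
    strata).  HDAC genes are shifted +``expr_effect`` in heavy Type-B
    co-twins only.  The designated NNAT-like gene is the first
    down-regulated signature gene.
    """
    cfg.validate()
    if cohort.truth is None or "pair_group" not in cohort.truth:
        raise ConfigurationError("cohort lacks truth pair_group labels")
    rng = _rng(cfg.seed, 2)
    genes = gene_names(cfg.n_genes)
    n_sig = cfg.n_signature_genes
    n_down = int(round(cfg.frac_signature_down * n_sig))
    roles = {}
    for i, g in enumerate(genes):
        if i < n_down:
            roles[g] = "signature_down"
        elif i < n_sig:
            roles[g] = "signature_up"
        elif i < n_sig + cfg.hdac_set_size:
            roles[g] = "hdac"
        else:
            roles[g] = "null"
    nnat_like = genes[0] if n_down > 0 else None

    individuals = cohort.individuals
    group_of_ind = {
        ind: cohort.truth["pair_group"][cohort.phenotypes.loc[ind, "pair"]]
        for ind in individuals
    }
    morph_of = cohort.truth.get("morph", {})

    baselines = rng.normal(7.0, 1.0, size=cfg.n_genes)
    X = baselines[:, None] + rng.normal(
        0.0, cfg.expr_noise_sd, size=(cfg.n_genes, len(individuals))
    )
    e = cfg.expr_effect
    role_arr = np.array([roles[g] for g in genes])
    sig_up = role_arr == "signature_up"
    sig_down = role_arr == "signature_down"
    hdac = role_arr == "hdac"
    for j, ind in enumerate(individuals):
        grp, mph = group_of_ind[ind], morph_of.get(ind, "light")
        if grp == "typeB":
            s = e if mph == "heavy" else -e
            X[sig_up, j] += s
            X[sig_down, j] -= s
            if mph == "heavy":
                X[hdac, j] += e
        elif grp == "intermediate":
            X[sig_up, j] += 0.5 * e
            X[sig_down, j] -= 0.5 * e

    expr = pd.DataFrame(X, index=genes, columns=individuals)
    expr.index.name = "gene"
    truth = dict(cohort.truth)
    truth["gene_role"] = roles
    truth["nnat_like_gene"] = nnat_like
    return TwinCohort(cohort.phenotypes, expr, list(cohort.trait_names), truth)


# ---------------------------------------------------------------------------
# mouse colony
# ---------------------------------------------------------------------------

def default_mouse_params() -> dict:
    """Per-genotype mixture components: (weight, (fat, lean) means g, sds g)."""
    wt = (1.0, (10.0, 25.0), (1.0, 1.5))
    heavy = (0.5, (25.0, 33.0), (2.0, 2.0))
    obese = (0.5, (22.0, 26.0), (2.0, 1.5))
    return {
        "WT": [wt],
        "NnatMut": [(0.5,) + wt[1:], heavy],
        "Trim28Mut": [(0.5,) + wt[1:], obese],
        "DoubleMut": [
            (1.0 / 3.0,) + wt[1:],
            (1.0 / 3.0,) + obese[1:],
            (1.0 / 3.0,) + heavy[1:],
        ],
    }


def simulate_mouse_colony(
    n_per_genotype, component_params: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Body-composition table with per-genotype Gaussian mixture structure.

    ``n_per_genotype`` is an int (same count for every genotype) or a dict
    genotype -> count.  ``component_params`` maps genotype -> list of
    ``(weight, (fat_mean, lean_mean), (fat_sd, lean_sd))``; weights must sum
    to 1 and the WT genotype must have exactly one component.  The planted
    morph of each animal (light/heavy/obese by component index) is recorded
    in ``truth_morph``.
    """
    params = component_params if component_params is not None else default_mouse_params()
    for geno, comps in params.items():
        w = [c[0] for c in comps]
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"component_params[{geno!r}]: weights must sum to 1"
            )
        for c in comps:
            if min(c[2]) <= 0:
                raise ConfigurationError(f"component_params[{geno!r}]: sds must be > 0")
        if len(comps) > len(MORPH_NAMES):
            raise ConfigurationError(
                f"component_params[{geno!r}]: at most {len(MORPH_NAMES)} components"
            )
    if "WT" in params and len(params["WT"]) != 1:
        raise ConfigurationError("WT must be configured with exactly 1 component")

    if isinstance(n_per_genotype, int):
        counts = {g: n_per_genotype for g in params}
    else:
        counts = dict(n_per_genotype)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    rows = []
    idx = 0
    for geno in params:
        comps = params[geno]
        weights = np.array([c[0] for c in comps])
        for _ in range(int(counts.get(geno, 0))):
            idx += 1
            k = int(rng.choice(len(comps), p=weights))
            _, (mf, ml), (sf, sl) = comps[k]
            fat = max(float(rng.normal(mf, sf)), 1e-3)
            lean = max(float(rng.normal(ml, sl)), 1e-3)
            rows.append(
                {
                    "animal": f"M{idx:04d}",
                    "genotype": geno,
                    "fat_mass": fat,
                    "lean_mass": lean,
                    "truth_morph": MORPH_NAMES[k],
                }
            )
    table = pd.DataFrame(
        rows, columns=["animal", "genotype", "fat_mass", "lean_mass", "truth_morph"]
    )
    return table
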
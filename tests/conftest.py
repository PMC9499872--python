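"""Shared fixtures: synthetic cohorts at two scales.

The small cohort (10 pairs per group, 300 genes) backs fast unit tests;
the default cohort (40 pairs per group, 2,000 genes) backs the recovery
tests that exercise the study-scale conditions.  Both are session-scoped
so the generators run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import twinupv as tw
from twinupv.cohort import DiscordanceMatrix, Orientation


def mz_discordance(cohort) -> tuple[Orientation, DiscordanceMatrix]:
    """Orient a cohort and return its MZ trait-discordance matrix."""
    ori = tw.assign_reference(cohort)
    traits = [t for t in cohort.trait_names if t != "insulin"]
    D = tw.trait_discordance(cohort, ori, traits).dropna_pairs()
    mz = [p for p in D.pairs if cohort.zygosity_of(p) == "MZ"]
    Dmz = DiscordanceMatrix(D.values.loc[mz], Orientation(ori.table.loc[mz]), "e")
    return ori, Dmz


@pytest.fixture(scope="session")
def small_cfg() -> tw.SimulationConfig:
    return tw.SimulationConfig(
        n_pairs_per_group={g: 10 for g in tw.simulate.GROUPS},
        n_dz_pairs=10,
        n_genes=300,
        n_signature_genes=24,
        hdac_set_size=16,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg) -> tw.TwinCohort:
    return tw.simulate_expression(small_cfg, tw.simulate_twin_cohort(small_cfg))


@pytest.fixture(scope="session")
def default_cfg() -> tw.SimulationConfig:
    return tw.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_cfg) -> tw.TwinCohort:
    return tw.simulate_expression(default_cfg, tw.simulate_twin_cohort(default_cfg))


@pytest.fixture(scope="session")
def default_oriented(default_cohort):
    return mz_discordance(default_cohort)


@pytest.fixture(scope="session")
def small_oriented(small_cohort):
    return mz_discordance(small_cohort)


def truth_groups(cohort, pairs) -> pd.Series:
    return pd.Series({p: cohort.truth["pair_group"][p] for p in pairs})


def heavy_typeb_individuals(cohort) -> set[str]:
    return {
        i
        for i in cohort.individuals
        if cohort.truth["morph"][i] == "heavy"
        and cohort.truth["pair_group"][cohort.phenotypes.loc[i, "pair"]] == "typeB"
    }


@pytest.fixture(scope="session")
def default_de(default_cohort, default_oriented):
    """Per-cluster DE tables on truth group labels (typed clusters)."""
    ori, Dmz = default_oriented
    labels = truth_groups(default_cohort, Dmz.pairs)
    return tw.paired_moderated_de(default_cohort.expression, ori, labels)
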
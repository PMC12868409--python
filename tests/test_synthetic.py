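"""Synthetic-community generator: determinism, design constants, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saprocom.data_model import TREE_SPECIES
from saprocom.diversity import mean_pairwise_distance
from saprocom.phylo import cophenetic_distance, tip_labels
from saprocom.synthetic import (SimulationConfig, default_schema,
                                simulate_dataset, simulate_emergence,
                                simulate_phylogeny, simulate_traits)
from saprocom.traits import gower_distance


class TestDesignConstants:
    def test_survey_layout_has_52_logs(self):
        """10 beech + 10 fir + 2x10 mixed + 12 spruce logs."""
        cfg = SimulationConfig()
        _, _, _, design, _, _ = simulate_dataset(cfg, seed=0)
        counts = design.logs["tree_species"].value_counts()
        assert len(design.log_ids) == 52
        assert counts["spruce"] == 12
        assert counts["beech"] == 20
        assert counts["fir"] == 20

    def test_spruce_offset_one_year(self):
        cfg = SimulationConfig()
        _, _, _, design, _, _ = simulate_dataset(cfg, seed=0)
        starts = design.logs.groupby("tree_species")["exposure_start"].unique()
        assert starts["spruce"] == [2013]
        assert starts["beech"] == [2012]
        assert starts["fir"] == [2012]

    def test_missing_sampling_year_2020(self):
        cfg = SimulationConfig()
        _, _, _, design, community, _ = simulate_dataset(cfg, seed=0)
        assert 2020 not in design.sampling_years
        assert 2020 in design.missing_years
        # spruce logs (start 2013) therefore never yield exposure year 7
        spruce = set(design.logs.loc[design.logs["tree_species"] == "spruce",
                                     "log_id"])
        yrs = set(community.records.loc[
            community.records["log_id"].isin(spruce), "exposure_year"])
        assert 7 not in yrs

    def test_determinism_under_seed(self):
        cfg = SimulationConfig(n_species=30, n_years=5, paper_design=False,
                               n_logs_per_tree=4)
        a = simulate_dataset(cfg, seed=5)
        b = simulate_dataset(cfg, seed=5)
        assert a[4] == b[4]  # identical community tables
        pd.testing.assert_frame_equal(a[1], b[1])  # identical traits


class TestTraits:
    def test_zero_rate_collapses_to_root_value(self):
        tree = simulate_phylogeny(12, 3)
        cfg = SimulationConfig(n_species=12, bm_rate=0.0, trait_noise=0.0)
        traits, _ = simulate_traits(tree, cfg, seed=1)
        # all continuous traits identical across species (root state)
        assert traits["wing_length"].nunique() == 1
        assert traits["body_length"].nunique() == 1

    def test_brownian_variance_grows_with_distance(self):
        """Squared trait difference larger for distant pairs (Monte Carlo)."""
        tree = simulate_phylogeny(10, 7)
        D = cophenetic_distance(tree)
        labels = list(D.index)
        iu = np.triu_indices(len(labels), 1)
        flat = D.to_numpy()[iu]
        close_pair = np.unravel_index(np.argmin(D.to_numpy() + np.eye(10) * 1e9),
                                      D.shape)
        far_pair = np.unravel_index(np.argmax(D.to_numpy()), D.shape)
        cfg = SimulationConfig(n_species=10, bm_rate=1.0, trait_noise=0.0)
        diffs_close, diffs_far = [], []
        for rep in range(500):
            tr, _ = simulate_traits(tree, cfg, seed=rep)
            v = tr["wing_length"]
            diffs_close.append((v.iloc[close_pair[0]] - v.iloc[close_pair[1]]) ** 2)
            diffs_far.append((v.iloc[far_pair[0]] - v.iloc[far_pair[1]]) ** 2)
        assert np.mean(diffs_far) > np.mean(diffs_close)

    def test_fast_markov_erases_clade_association(self):
        """At a high transition rate, categorical states are independent of
        the deepest split (chi-square association ~ null)."""
        tree = simulate_phylogeny(60, 11)
        root_children = tree.seed_node.child_nodes()
        clade = set()
        for lf in root_children[0].leaf_iter():
            clade.add(lf.taxon.label)
        cfg = SimulationConfig(n_species=60, markov_rate=50.0)
        pvals = []
        for rep in range(30):
            tr, _ = simulate_traits(tree, cfg, seed=100 + rep)
            inside = tr.index.isin(clade)
            ct = pd.crosstab(inside, tr["feeding_type"])
            if ct.shape != (2, 3):
                continue
            pvals.append(stats.chi2_contingency(ct).pvalue)
        # uniform p-values under independence: mean near 0.5
        assert 0.3 < np.mean(pvals) < 0.7

    def test_schema_covers_17_traits(self):
        schema = default_schema()
        assert len(schema.traits) == 17
        kinds = pd.Series(schema.types)
        assert (kinds == "continuous").sum() == 13
        assert (kinds == "categorical").sum() == 4


class TestEmergence:
    def test_counts_positive_integers(self, small_dataset):
        _, _, _, _, community, _ = small_dataset
        assert (community.records["count"] >= 1).all()
        assert community.records["count"].dtype.kind == "i"

    def test_flat_symmetric_config_equal_year_totals(self):
        """With no decay, no filter and flat niches, yearly totals are
        exchangeable (Kruskal-Wallis across years not rejected)."""
        cfg = SimulationConfig(n_species=40, n_years=6, paper_design=False,
                               n_logs_per_tree=6, decay_rate=0.0,
                               early_filter_strength=0.0, flat_niches=True)
        totals = []
        for seed in range(30):
            _, _, _, design, community, _ = simulate_dataset(cfg, seed)
            per_year = community.records.groupby("exposure_year")["count"].sum()
            totals.append(per_year.loc[[1, 2, 3, 4, 5]].to_numpy())
        totals = np.array(totals)
        stat = stats.kruskal(*totals.T)
        assert stat.pvalue > 0.01

    def test_decay_rate_recovered_from_slope(self):
        """Log-linear slope of beech/fir yearly totals ~ -delta."""
        delta = 0.35
        cfg = SimulationConfig(n_species=150, n_years=10, paper_design=False,
                               n_logs_per_tree=12, decay_rate=delta,
                               early_filter_strength=0.0, flat_niches=True,
                               theta=5.0)
        slopes = []
        for seed in range(8):
            _, _, _, design, community, _ = simulate_dataset(cfg, seed)
            # restrict to beech/fir logs so every year aggregates the same
            # set of logs (spruce is offset and sees different years)
            bf = set(design.logs.loc[design.logs["tree_species"] != "spruce",
                                     "log_id"])
            rec = community.records[community.records["log_id"].isin(bf)]
            per_year = rec.groupby("exposure_year")["count"].sum()
            yrs = per_year.index.to_numpy(float)
            res = stats.linregress(yrs, np.log(per_year.to_numpy()))
            slopes.append(res.slope)
        est = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(est + delta) < 2 * max(se, 0.02)

    def test_early_filter_clusters_trait_space(self):
        """gamma >> 0 lowers year-1 observed functional MPD vs gamma = 0."""
        def early_mpd(gamma, seed):
            cfg = SimulationConfig(n_species=60, n_years=5, paper_design=False,
                                   n_logs_per_tree=6, filter_mode="traits",
                                   early_filter_strength=gamma)
            tree, traits, schema, design, community, _ = simulate_dataset(cfg, seed)
            D = gower_distance(traits, schema)
            vals = []
            for log_id in design.log_ids:
                asm = community.assemblage(log_id, 1)
                if len(asm) >= 2:
                    vals.append(mean_pairwise_distance(list(asm), D))
            return np.mean(vals)

        filtered = [early_mpd(10.0, s) for s in range(6)]
        neutral = [early_mpd(0.0, s) for s in range(6)]
        assert np.mean(filtered) < np.mean(neutral)

    def test_truth_records_parameters(self, small_dataset):
        _, _, _, _, _, truth = small_dataset
        assert truth.decay_rate == pytest.approx(0.35)
        assert set(truth.mu) == set(truth.sigma)
        assert all(s >= 0 for s in truth.sigma.values())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_species=2)
        with pytest.raises(ValueError):
            SimulationConfig(early_filter_strength=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(filter_mode="magic")
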
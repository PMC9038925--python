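"""Cross-species peak conversion chain, guided clustering and nulls."""

import numpy as np
import pandas as pd
import pytest

from atacstrat.crossmap import (
    HomologMap,
    guided_clustering_agreement,
    map_unique_peaks_cross_species,
    motif_overlap_control,
    random_peak_control,
    rank_motifs_by_enrichment,
)
from atacstrat.linkage import candidate_peak_gene_pairs, link_peaks_to_genes
from atacstrat.matrixio import annotate_peaks
from atacstrat.synth import CohortConfig, generate_paired_species

MOUSE_CFG = dict(
    n_peaks=1500,
    n_genes=200,
    n_motifs=45,
    samples_per_cluster=(3, 3, 3),
    frac_cluster_specific=0.03,
    dre_bias=1.0,
    link_noise_sd=0.0,
    frac_background_linked=0.0,
)
HUMAN_CFG = dict(
    n_peaks=3000,
    n_genes=400,
    n_motifs=45,
    samples_per_cluster=(12, 12, 12),
    frac_cluster_specific=0.015,
    dre_bias=1.0,
    link_noise_sd=0.0,
    frac_background_linked=0.0,
)


@pytest.fixture(scope="module")
def paired():
    mouse, human, hom = generate_paired_species(
        CohortConfig(**MOUSE_CFG, seed=51),
        CohortConfig(**HUMAN_CFG, seed=52),
        shared_program_frac=1.0,
        seed=53,
    )
    m_ann = annotate_peaks(mouse.peaks, mouse.genes)
    pairs = candidate_peak_gene_pairs(human.peaks, human.genes)
    links = link_peaks_to_genes(human.counts.logcpm, human.expression, pairs)
    return mouse, human, hom, m_ann, links


class TestHomologMap:
    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError):
            HomologMap(pd.DataFrame({"gene_a": ["g1"], "gene_b": ["g1"]}))

    def test_bidirectional_lookup_and_multiplicity(self):
        hom = HomologMap(
            pd.DataFrame({"gene_a": ["m1", "m2"], "gene_b": ["h1", "h2"]})
        )
        assert hom.a_to_b()["m1"] == "h1"
        assert hom.b_to_a()["h2"] == "m2"
        assert not hom.multiplicity_flags()["a_multi"].any()


class TestMappingChain:
    def test_gene_without_homolog_gives_empty_chain(self, paired):
        mouse, human, hom, m_ann, links = paired
        # a background mouse peak annotated to a free gene with no homolog
        free = set(m_ann["nearest_gene_id"]) - set(hom.pairs["gene_a"])
        if free:
            peak = m_ann[m_ann["nearest_gene_id"].isin(free)].index[0]
            res = map_unique_peaks_cross_species([peak], m_ann, hom, links)
            assert res.step_counts["homolog_genes"] == 0
            assert res.human_peaks == []

    def test_unknown_peak_empty_not_exception(self, paired):
        mouse, human, hom, m_ann, links = paired
        res = map_unique_peaks_cross_species(["nope"], m_ann, hom, links)
        assert res.step_counts["mouse_genes"] == 0
        assert res.human_peaks == []

    def test_full_sharing_noiseless_maps_to_planted_peaks(self, paired):
        mouse, human, hom, m_ann, links = paired
        mouse_unique = sum(mouse.cluster_specific_peaks.values(), [])
        res = map_unique_peaks_cross_species(mouse_unique, m_ann, hom, links)
        planted = {p for p, _ in human.true_links}
        assert set(res.human_peaks) == planted

    def test_step_counts_match_relational_join_oracle(self, paired):
        mouse, human, hom, m_ann, links = paired
        rng = np.random.default_rng(2)
        peaks = list(rng.choice(m_ann.index.to_numpy(), size=200, replace=False))
        res = map_unique_peaks_cross_species(peaks, m_ann, hom, links)
        # brute-force chained join with plain set algebra
        genes = {m_ann.loc[p, "nearest_gene_id"] for p in peaks} - {None}
        fwd = dict(zip(hom.pairs["gene_a"], hom.pairs["gene_b"]))
        homs = {fwd[g] for g in genes if g in fwd}
        sig = links[links["significant"]]
        linked = sig[sig["gene_id"].isin(homs)]
        assert res.step_counts["mouse_genes"] == len(genes)
        assert res.step_counts["homolog_genes"] == len(homs)
        assert res.step_counts["linked_genes"] == linked["gene_id"].nunique()
        assert set(res.human_peaks) == set(linked["peak_id"])


class TestGuidedClustering:
    def test_planted_peaks_reproduce_reference(self, paired):
        mouse, human, hom, m_ann, links = paired
        planted = [p for p, _ in human.true_links]
        out = guided_clustering_agreement(
            human.counts.logcpm,
            planted,
            human.true_labels,
            k=3,
            n_runs=4,
            seed=7,
            max_iter=300,
        )
        assert out["matched_agreement"] == 1.0
        assert out["ari"] == 1.0

    def test_uninformative_peaks_low_agreement(self, paired):
        mouse, human, hom, m_ann, links = paired
        planted = {p for p, _ in human.true_links}
        noise_peaks = [p for p in human.counts.raw.index if p not in planted][:150]
        out = guided_clustering_agreement(
            human.counts.logcpm,
            noise_peaks,
            human.true_labels,
            k=3,
            n_runs=4,
            seed=8,
            max_iter=300,
        )
        assert out["ari"] < 0.3

    def test_too_few_peaks_rejected(self, paired):
        mouse, human, hom, m_ann, links = paired
        with pytest.raises(ValueError):
            guided_clustering_agreement(
                human.counts.logcpm, ["peak000000"], human.true_labels, k=3
            )


class TestRandomPeakControl:
    def test_degenerate_universe_equals_observed(self, paired):
        mouse, human, hom, m_ann, links = paired
        planted = [p for p, _ in human.true_links]
        obs = guided_clustering_agreement(
            human.counts.logcpm, planted, human.true_labels, k=3, n_runs=4,
            seed=1, max_iter=300,
        )["matched_agreement"]
        null = random_peak_control(
            human.counts.logcpm,
            planted,
            set_size=len(planted),
            reference_labels=human.true_labels,
            k=3,
            n_iter=3,
            seed=2,
            observed=obs,
            n_runs=4,
            max_iter=300,
        )
        assert np.allclose(null.values, obs)

    def test_planted_exceeds_null(self, paired):
        mouse, human, hom, m_ann, links = paired
        planted = [p for p, _ in human.true_links]
        universe = list(links["peak_id"].unique())
        obs = guided_clustering_agreement(
            human.counts.logcpm, planted, human.true_labels, k=3, n_runs=4,
            seed=3, max_iter=300,
        )["matched_agreement"]
        null = random_peak_control(
            human.counts.logcpm,
            universe,
            set_size=min(len(planted), len(universe)),
            reference_labels=human.true_labels,
            k=3,
            n_iter=15,
            seed=4,
            observed=obs,
        )
        assert obs > null.mean
        assert null.percentile >= 80.0

    def test_set_size_validation(self, paired):
        mouse, human, hom, m_ann, links = paired
        with pytest.raises(ValueError):
            random_peak_control(
                human.counts.logcpm, ["p1"], 5, human.true_labels, k=3, n_iter=1
            )


class TestMotifOverlap:
    def test_enrichment_ranking_prefers_program_motifs(self, paired):
        mouse, human, hom, m_ann, links = paired
        peaks = mouse.cluster_specific_peaks[0]
        ranking = rank_motifs_by_enrichment(peaks, mouse.motif_membership)
        top = set(ranking.index[:10])
        assert top == mouse.true_motif_programs[0]

    def test_shared_program_full_overlap_and_no_null(self, paired):
        # one cluster's peaks carry a single shared 10-motif program, so
        # the top-10 enrichment ranks coincide across species
        mouse, human, hom, m_ann, links = paired
        out = motif_overlap_control(
            mouse.cluster_specific_peaks[0],
            mouse.motif_membership,
            human.motif_membership,
            m_ann,
            hom,
            links,
            k=10,
            n_iter=0,
        )
        assert out["observed_overlap"] >= 8
        assert out["null_mean"] is None

    def test_null_control_runs_and_is_lower(self, paired):
        mouse, human, hom, m_ann, links = paired
        out = motif_overlap_control(
            mouse.cluster_specific_peaks[0],
            mouse.motif_membership,
            human.motif_membership,
            m_ann,
            hom,
            links,
            k=10,
            n_iter=10,
            seed=5,
        )
        assert out["null_mean"] < out["observed_overlap"]

    def test_empty_shared_namespace_rejected(self, paired):
        mouse, human, hom, m_ann, links = paired
        other = human.motif_membership.rename(columns=lambda c: "x" + c)
        with pytest.raises(ValueError, match="shared motif namespace"):
            motif_overlap_control(
                ["p"], mouse.motif_membership, other, m_ann, hom, links
            )
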
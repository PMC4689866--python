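"""Generator correctness: determinism, calibration, planted structure."""

import numpy as np
import pytest

import mybnet as m


def test_same_seed_bit_identical():
    cfg = m.SyntheticConfig(seed=42, planted_motifs=(("g0001", "MBS_TAACTG", "+", 10),))
    a = m.generate_all(cfg)
    b = m.generate_all(m.SyntheticConfig(seed=42,
                                         planted_motifs=(("g0001", "MBS_TAACTG", "+", 10),)))
    assert a[0].values.equals(b[0].values)
    assert a[1].term_to_genes == b[1].term_to_genes
    assert a[2].sequences == b[2].sequences
    assert a[3].module_of_gene == b[3].module_of_gene
    assert a[3].deg_genes == b[3].deg_genes


def test_different_seed_differs():
    a, _ = m.generate_expression(m.SyntheticConfig(seed=1))
    b, _ = m.generate_expression(m.SyntheticConfig(seed=2))
    assert not a.values.equals(b.values)


def test_zero_noise_within_module_pcc_is_exactly_one():
    cfg = m.SyntheticConfig(noise_sd=0.0, anticorrelated_fraction=0.0,
                            n_deg_genes=0, seed=5)
    matrix, truth = m.generate_expression(cfg)
    g1, g2 = [g for g, mod in truth.module_of_gene.items() if mod == 1][:2]
    r = np.corrcoef(matrix.values.loc[g1], matrix.values.loc[g2])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_zero_noise_flipped_member_pcc_is_minus_one():
    cfg = m.SyntheticConfig(noise_sd=0.0, anticorrelated_fraction=0.3,
                            n_deg_genes=0, seed=5)
    matrix, truth = m.generate_expression(cfg)
    mod1 = [g for g, mod in truth.module_of_gene.items() if mod == 1]
    flipped = [g for g in mod1 if g in truth.flipped_genes]
    straight = [g for g in mod1 if g not in truth.flipped_genes]
    r = np.corrcoef(matrix.values.loc[straight[0]], matrix.values.loc[flipped[0]])[0, 1]
    assert r == pytest.approx(-1.0, abs=1e-12)


def test_loading_calibration_hits_target_correlation():
    """Monte-Carlo check of lambda^2/(lambda^2+sigma^2) = r: mean within-module
    |PCC| over ~1000 pairs lands in [0.85, 0.95] for a 0.9 target."""
    cfg = m.SyntheticConfig(n_genes=60, n_background_genes=0, module_sizes=(60,),
                            anticorrelated_fraction=0.0, n_conditions=10,
                            replicates_per_condition=2,
                            within_module_correlation=0.9, n_deg_genes=0, seed=7)
    matrix, _ = m.generate_expression(cfg)
    r = np.corrcoef(matrix.values.to_numpy())
    vals = np.abs(r[np.triu_indices(60, 1)])
    assert len(vals) > 1000
    assert 0.85 <= vals.mean() <= 0.95


def test_background_pairs_uncorrelated_on_average():
    cfg = m.SyntheticConfig(seed=9, n_deg_genes=0)
    matrix, truth = m.generate_expression(cfg)
    bg = [g for g, mod in truth.module_of_gene.items() if mod is None]
    r = np.corrcoef(matrix.values.loc[bg].to_numpy())
    off = r[np.triu_indices(len(bg), 1)]
    assert abs(off.mean()) < 0.1


def test_deg_effect_planted_in_treatment_condition():
    cfg = m.SyntheticConfig(seed=3, deg_effect=2.0)
    matrix, truth = m.generate_expression(cfg)
    g = sorted(truth.deg_genes)[0]
    trt = matrix.samples_for(truth.treatment_condition)
    ctl = [s for s in matrix.sample_ids if s not in trt]
    diff = matrix.values.loc[g, trt].mean() - matrix.values.loc[g, ctl].mean()
    assert diff == pytest.approx(2.0, abs=1.5)  # noise_sd=1 on 3 replicates


@pytest.mark.parametrize(
    "coverage,size,expected",
    [(1.0, 10, 10), (0.5, 10, 5)],
)
def test_annotation_coverage_counts(coverage, size, expected):
    cfg = m.SyntheticConfig(n_genes=size + 20, n_background_genes=20,
                            module_sizes=(size,), annotation_coverage=coverage,
                            n_noise_terms=0, n_deg_genes=0, seed=1)
    _, truth = m.generate_expression(cfg)
    ann = m.generate_annotations(truth, cfg)
    term = truth.term_of_module[1]
    module_genes = {g for g, mod in truth.module_of_gene.items() if mod == 1}
    assert len(ann.term_to_genes[term]) == expected
    assert ann.term_to_genes[term] <= module_genes
    if coverage == 1.0:
        assert ann.term_to_genes[term] == frozenset(module_genes)


def test_no_noise_terms_means_one_term_per_module():
    cfg = m.SyntheticConfig(n_noise_terms=0, seed=1)
    _, truth = m.generate_expression(cfg)
    ann = m.generate_annotations(truth, cfg)
    assert len(ann.term_to_genes) == len(cfg.module_sizes)
    assert set(truth.term_of_module.values()) == set(ann.term_to_genes)


def test_low_coverage_warns():
    cfg = m.SyntheticConfig(n_genes=33, n_background_genes=30, module_sizes=(3,),
                            annotation_coverage=0.4, n_deg_genes=0, seed=1)
    _, truth = m.generate_expression(cfg)
    with pytest.warns(UserWarning, match="annotation_coverage"):
        m.generate_annotations(truth, cfg)


def test_planted_motif_reads_verbatim():
    cfg = m.SyntheticConfig(seed=4, planted_motifs=(("g0001", "MBS_TAACTG", "+", 521),))
    _, _, proms, truth = m.generate_all(cfg)
    assert proms.sequences["g0001"][520:526] == "TAACTG"
    assert m.MotifHit("g0001", "MBS_TAACTG", "+", 521, "MBS-drought") in truth.planted_hits


def test_minus_strand_plant_inserts_reverse_complement():
    cfg = m.SyntheticConfig(seed=4, planted_motifs=(("g0002", "MBS_CAACTG", "-", 100),))
    _, _, proms, _ = m.generate_all(cfg)
    assert proms.sequences["g0002"][99:105] == "CAGTTG"


def test_background_motif_count_matches_binomial_model():
    """Spurious plus-strand TAACTG occurrences on 100 kb of uniform sequence
    stay within 3 sigma of n_positions * (1/4)^6."""
    cfg = m.SyntheticConfig(seed=13)
    _, truth = m.generate_expression(cfg)
    proms, _ = m.generate_promoters(truth, cfg)
    count = sum(s.count("TAACTG") for s in proms.sequences.values())
    n_pos = 100 * (1000 - 6 + 1)
    p = 0.25**6
    mean, sd = n_pos * p, np.sqrt(n_pos * p * (1 - p))
    assert abs(count - mean) <= 3 * sd


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(module_sizes=(2, 68), n_background_genes=30), "module sizes"),
        (dict(n_background_genes=29), "must equal n_genes"),
        (dict(anticorrelated_fraction=1.5), "anticorrelated_fraction"),
        (dict(within_module_correlation=1.0), "within_module_correlation"),
        (dict(base_composition=(0.5, 0.5, 0.0, 0.1)), "base_composition"),
        (dict(n_deg_genes=31), "n_deg_genes"),
    ],
)
def test_invalid_configs_rejected(kwargs, match):
    with pytest.raises(ValueError, match=match):
        m.SyntheticConfig(**kwargs)


def test_overlapping_plants_rejected():
    cfg = m.SyntheticConfig(seed=1, planted_motifs=(("g0001", "MBS_TAACTG", "+", 100),
                                                    ("g0001", "MBS_CAACTG", "+", 103)))
    _, truth = m.generate_expression(cfg)
    with pytest.raises(ValueError, match="overlapping"):
        m.generate_promoters(truth, cfg)


def test_out_of_bounds_plant_rejected():
    cfg = m.SyntheticConfig(seed=1, planted_motifs=(("g0001", "MBS_TAACTG", "+", 998),))
    _, truth = m.generate_expression(cfg)
    with pytest.raises(ValueError, match="out of bounds"):
        m.generate_promoters(truth, cfg)
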
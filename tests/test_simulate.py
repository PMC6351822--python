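"""Simulator: genome layout, protection tracks, fragment sampling, truth."""

import numpy as np
import pytest

from cffrag.simulate import (
    SUBCOMPARTMENTS,
    CohortTruth,
    FragmentLengthModel,
    Gene,
    GenomeConfig,
    GroupParams,
    build_genome_model,
    default_groups,
    derive_sample_seed,
    marker_genes,
    protection_profile,
    simulate_cohort,
    simulate_fragments,
    simulate_tissue_expression,
)

SMALL = GenomeConfig(
    chromosomes=(("chr1", 1_000_000),), n_genes=10, n_ctcf=5, n_repeats=4, seed=7
)


def flat_group(**overrides) -> GroupParams:
    kwargs = dict(
        name="g",
        compartment_weights={l: 1.0 for l in SUBCOMPARTMENTS},
        ndr_depth=0.5,
        phasing_amplitude=0.5,
        repeat_5p_weight=1.0,
        tissue_mixture={},
    )
    kwargs.update(overrides)
    return GroupParams(**kwargs)


def small_expression(model, seed=8):
    return simulate_tissue_expression(
        len(model.genes), 3, seed=seed, gene_ids=[g.gene_id for g in model.genes]
    )


def test_genome_model_is_deterministic_and_valid():
    m1 = build_genome_model(SMALL)
    m2 = build_genome_model(SMALL)
    m1.validate()
    assert [g.gene_id for g in m1.genes] == [g.gene_id for g in m2.genes]
    assert m1.bin_labels.equals(m2.bin_labels)
    assert len(m1.genes) == 10
    assert len(m1.ctcf_sites) == 5
    assert len(m1.repeats) == 4


def test_gene_strand_convention():
    with pytest.raises(ValueError):
        Gene("g", "chr1", 100, 50, "+")
    with pytest.raises(ValueError):
        Gene("g", "chr1", 50, 100, "-")
    model = build_genome_model(SMALL)
    for g in model.genes:
        if g.strand == "+":
            assert g.tss < g.tts
        else:
            assert g.tss > g.tts


def test_bin_labels_cover_subcompartments_evenly():
    model = build_genome_model(GenomeConfig(seed=3))
    counts = model.bin_labels["label"].value_counts()
    assert set(counts.index) == set(SUBCOMPARTMENTS)
    assert counts.max() - counts.min() <= 1


def test_expression_marker_blocks():
    expr = simulate_tissue_expression(40, 5, seed=1)
    assert expr.shape == (5, 40)
    assert (expr.to_numpy() > 0).all()
    for t in expr.index:
        markers = marker_genes(expr, t)
        assert len(markers) == 8
        # marker expression clearly dominates the tissue's background
        assert expr.loc[t, markers].min() > expr.drop(index=t)[markers].to_numpy().max() / 4
    blocks = [frozenset(marker_genes(expr, t)) for t in expr.index]
    assert len(set(blocks)) == 5  # disjoint blocks
    for a in blocks:
        for b in blocks:
            assert a is b or not (a & b) or a != b


def test_length_model_respects_bounds(rng):
    flm = FragmentLengthModel()
    lengths = flm.sample(2000, rng)
    assert lengths.min() >= 100
    assert lengths.max() <= 400
    assert abs(lengths.mean() - 170) < 2


def test_protection_profile_flat_when_nothing_planted():
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    gp = flat_group(ndr_depth=0.0, phasing_amplitude=0.0, repeat_5p_weight=1.0)
    track = protection_profile(model, gp, expr)["chr1"]
    assert np.allclose(track, track[0])


def test_protection_profile_full_depletion_zeroes_tss():
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    gp = flat_group(ndr_depth=1.0, phasing_amplitude=0.0)
    track = protection_profile(model, gp, expr)["chr1"]
    for g in model.genes:
        assert track[g.tss] == pytest.approx(0.0, abs=1e-12)


def test_protection_profile_ndr_depth_monotone_at_tss():
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    values = []
    for d in (0.2, 0.5, 0.8):
        track = protection_profile(model, flat_group(ndr_depth=d, phasing_amplitude=0.0), expr)["chr1"]
        values.append(np.mean([track[g.tss] for g in model.genes]))
    assert values[0] > values[1] > values[2]


def test_protection_profile_has_planted_spacing():
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    track = protection_profile(model, flat_group(ndr_depth=0.0), expr)["chr1"]
    gene = next(g for g in model.genes if g.strand == "+")
    seg = track[gene.tss : gene.tss + 9800]
    seg = seg - seg.mean()
    spec = np.abs(np.fft.rfft(seg)) ** 2
    freqs = np.fft.rfftfreq(seg.size)
    peak_period = 1.0 / freqs[1:][np.argmax(spec[1:])]
    assert 194 <= peak_period <= 198


def test_protection_profile_minus_strand_mirrors_downstream():
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    track = protection_profile(model, flat_group(ndr_depth=0.0), expr)["chr1"]
    gene = next(g for g in model.genes if g.strand == "-")
    # downstream of a minus-strand TSS runs toward lower coordinates
    downstream = track[gene.tss - 3000 : gene.tss + 1][::-1]
    upstream = track[gene.tss : gene.tss + 3001]
    assert np.var(downstream) > np.var(upstream)


def test_simulate_fragments_depth_and_bounds():
    track = np.ones(50_000)
    lib = simulate_fragments(track, depth=500, seed=4)
    assert lib.library_size == 500
    for r in lib.records:
        assert 0 <= r.start < r.end <= 50_000
    starts = [r.start for r in lib.records]
    assert starts == sorted(starts)


def test_simulate_fragments_deterministic():
    track = np.ones(20_000)
    a = simulate_fragments(track, depth=200, seed=9)
    b = simulate_fragments(track, depth=200, seed=9)
    assert [(r.start, r.end) for r in a.records] == [(r.start, r.end) for r in b.records]
    c = simulate_fragments(track, depth=200, seed=10)
    assert [(r.start, r.end) for r in c.records] != [(r.start, r.end) for r in a.records]


def test_simulate_fragments_follows_track_mass():
    track = np.zeros(20_000)
    track[:10_000] = 3.0
    track[10_000:] = 1.0
    lib = simulate_fragments(track, depth=4000, seed=5)
    mids = np.array([r.midpoint for r in lib.records])
    frac_left = np.mean(mids < 10_000)
    assert abs(frac_left - 0.75) < 0.03


def test_simulate_fragments_zero_track_errors():
    with pytest.raises(ValueError):
        simulate_fragments(np.zeros(1000), depth=10)
    empty = simulate_fragments(np.zeros(1000), depth=0)
    assert empty.library_size == 0


def test_derive_sample_seed_stable_and_distinct():
    assert derive_sample_seed(1, 0) == derive_sample_seed(1, 0)
    seeds = {derive_sample_seed(1, i) for i in range(20)}
    assert len(seeds) == 20


def test_simulate_cohort_structure_and_truth_round_trip(tmp_path):
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    groups = [flat_group(name="a"), flat_group(name="b", ndr_depth=0.8)]
    libs, truth = simulate_cohort(groups, 2, model, expr, depth=1000, seed=11)
    assert [lib.group for lib in libs] == ["a", "a", "b", "b"]
    assert all(lib.library_size == 1000 for lib in libs)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = CohortTruth.from_json(path)
    assert [s.sample_id for s in back.samples] == [s.sample_id for s in truth.samples]
    assert back.group_params["a"]["ndr_depth"] == 0.5
    assert back.spacing == truth.spacing


def test_simulate_cohort_rejects_duplicate_group_names():
    model = build_genome_model(SMALL)
    expr = small_expression(model)
    with pytest.raises(ValueError):
        simulate_cohort([flat_group(), flat_group()], 1, model, expr, depth=10)


def test_group_params_validation():
    with pytest.raises(ValueError):
        flat_group(ndr_depth=1.5)
    with pytest.raises(ValueError):
        flat_group(tissue_mixture={"a": 0.5, "b": 0.6})
    with pytest.raises(ValueError):
        flat_group(tissue_mixture={"a": -0.2, "b": 1.2})


def test_default_groups_doubling_structure():
    groups = {g.name: g for g in default_groups()}
    focal = "tissue4"
    young = groups["young"].tissue_mixture
    old = groups["old"].tissue_mixture
    assert young[focal] == min(young.values())
    assert old[focal] == max(old.values())
    # raw doubling before renormalization
    ratio = (old[focal] / old["tissue0"]) / (young[focal] / young["tissue0"])
    assert ratio == pytest.approx(2.0)
    assert sum(young.values()) == pytest.approx(1.0)
    assert sum(old.values()) == pytest.approx(1.0)
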
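"""Profile-HMM construction arithmetic, Viterbi/forward against a
path-enumeration oracle, calibration, classification and seed collection."""

import math

import numpy as np
import pytest

from hrsurvey.msa import MultipleAlignment
from hrsurvey.phmm import (DomainHit, EmptyModelError, ProfileHMM, build_phmm,
                           calibrate_evalue, classify_coverage, collect_seed,
                           forward_score, read_phmm, viterbi_scan, write_phmm)
from hrsurvey.scoring import AMINO_ACIDS, ScoringScheme
from hrsurvey.synth import make_default_templates, mutate_from_template

LN2 = math.log(2.0)


def _random_model(rng, n_nodes):
    match = rng.dirichlet(np.ones(20) * 0.5, size=n_nodes)
    bg = np.full(20, 0.05)
    insert = np.tile(bg, (n_nodes + 1, 1))
    t = {}
    mmi = rng.dirichlet(np.ones(3), size=n_nodes)
    t["tMM"], t["tMI"], t["tMD"] = mmi[:, 0], mmi[:, 1], mmi[:, 2]
    im = rng.dirichlet(np.ones(2), size=n_nodes)
    t["tIM"], t["tII"] = im[:, 0], im[:, 1]
    dm = rng.dirichlet(np.ones(2), size=n_nodes)
    t["tDM"], t["tDD"] = dm[:, 0], dm[:, 1]
    return ProfileHMM("rnd", match, insert, t, bg)


def _enumerate_paths(model, seq):
    """All legal local state paths with their log-odds scores (nats).

    Independent of the DP: explicit recursion over (state, node, next
    position), delete chains included.  Returns (best, logsumexp) over
    complete paths.
    """
    code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    x = [code[c] for c in seq]
    M = model.node_count
    em = np.log(model.match_emissions) - np.log(model.background)
    ei = np.log(model.insert_emissions[1:]) - np.log(model.background)
    lt = {k: np.log(v) for k, v in model.transitions.items()}
    entry = exit_ = -math.log(M)
    scores = []

    def from_match(k, i, acc):
        scores.append(acc + exit_)
        if i + 1 < len(x):
            if k + 1 < M:
                from_match(k + 1, i + 1,
                           acc + lt["tMM"][k] + em[k + 1, x[i + 1]])
            from_insert(k, i + 1, acc + lt["tMI"][k] + ei[k, x[i + 1]])
            # delete chains of every length
            run = lt["tMD"][k]
            for d_end in range(k + 1, M - 1):
                from_match(d_end + 1, i + 1,
                           acc + run + lt["tDM"][d_end] + em[d_end + 1, x[i + 1]])
                run += lt["tDD"][d_end]

    def from_insert(k, i, acc):
        if i + 1 < len(x):
            if k + 1 < M:
                from_match(k + 1, i + 1,
                           acc + lt["tIM"][k] + em[k + 1, x[i + 1]])
            from_insert(k, i + 1, acc + lt["tII"][k] + ei[k, x[i + 1]])

    for i in range(len(x)):
        for k in range(M):
            from_match(k, i, entry + em[k, x[i]])
    best = max(scores)
    total = best + math.log(sum(math.exp(s - best) for s in scores))
    return best, total


class TestBuild:
    def test_gap_free_width_equals_nodes(self):
        aln = MultipleAlignment([("a", "HEAGA"), ("b", "HEWGA"), ("c", "HEAGA")])
        model = build_phmm(aln)
        assert model.node_count == 5

    def test_gappy_column_becomes_insert(self):
        aln = MultipleAlignment([("a", "HEA"), ("b", "H-A"), ("c", "H-A")])
        model = build_phmm(aln, match_rule=0.5)
        assert model.node_count == 2

    def test_anchor_weight_arithmetic(self):
        # column counts {H:3, N:1}; anchor weight 5 -> e(H) = 16/36
        aln = MultipleAlignment([("a", "AH"), ("b", "AH"), ("c", "AH"),
                                 ("d", "AN")])
        model = build_phmm(aln, pseudocount=1.0, anchors=[(1, "H", 5.0)])
        h = AMINO_ACIDS.index("H")
        assert model.match_emissions[1, h] == pytest.approx(16 / 36)

    def test_normalisation_invariants(self, hr_profile):
        model = hr_profile[0]
        assert np.allclose(model.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.insert_emissions.sum(axis=1), 1.0, atol=1e-9)
        t = model.transitions
        assert np.allclose(t["tMM"] + t["tMI"] + t["tMD"], 1.0, atol=1e-9)
        assert np.allclose(t["tIM"] + t["tII"], 1.0, atol=1e-9)
        assert np.allclose(t["tDM"] + t["tDD"], 1.0, atol=1e-9)

    def test_all_gappy_columns_error(self):
        aln = MultipleAlignment([("a", "A--"), ("b", "-A-"), ("c", "--A")])
        with pytest.raises(EmptyModelError):
            build_phmm(aln, match_rule=0.5)


class TestViterbiOracle:
    def test_viterbi_matches_path_enumeration(self):
        rng = np.random.default_rng(7)
        AA = list(AMINO_ACIDS)
        for case in range(100):
            model = _random_model(rng, int(rng.integers(1, 4)))
            seq = "".join(rng.choice(AA, rng.integers(1, 5)))
            best, _ = _enumerate_paths(model, seq)
            hit = viterbi_scan(model, seq, floor=-1e9)
            assert hit.bit_score == pytest.approx(best / LN2, abs=1e-9)

    def test_forward_matches_path_enumeration(self):
        rng = np.random.default_rng(8)
        AA = list(AMINO_ACIDS)
        for case in range(50):
            model = _random_model(rng, int(rng.integers(1, 4)))
            seq = "".join(rng.choice(AA, rng.integers(1, 5)))
            _, total = _enumerate_paths(model, seq)
            assert forward_score(model, seq) == pytest.approx(total / LN2,
                                                              abs=1e-8)

    def test_forward_at_least_viterbi(self, hr_profile):
        model, hr, _, _ = hr_profile
        for seed in range(5):
            seq = mutate_from_template(hr, 0.6, 300 + seed)
            v = viterbi_scan(model, seq, floor=-1e9).bit_score
            f = forward_score(model, seq)
            assert f >= v - 1e-6

    def test_uniform_single_node_zero_emission_logodds(self):
        bg = np.full(20, 0.05)
        t = {k: np.array([v]) for k, v in
             [("tMM", 1.0), ("tMI", 0.0), ("tMD", 0.0), ("tIM", 1.0),
              ("tII", 0.0), ("tDM", 1.0), ("tDD", 0.0)]}
        model = ProfileHMM("flat", bg[None, :], np.tile(bg, (2, 1)), t, bg)
        hit = viterbi_scan(model, "W", floor=-1e9)
        # emission log-odds 0; only entry/exit (=0 for a 1-node model) remain
        assert hit.bit_score == pytest.approx(0.0, abs=1e-9)

    def test_consensus_full_coverage(self, hr_profile):
        model, hr, _, _ = hr_profile
        hit = viterbi_scan(model, hr.consensus)
        assert hit.reference_coverage == pytest.approx(1.0)
        assert hit.query_envelope == (0, 118)


class TestCalibrationAndClassification:
    def test_evalue_limits(self, hr_profile):
        model = hr_profile[0]
        calib = calibrate_evalue(model, n_random=100, length=100, seed=0)
        assert calib.evalue(1e6, 10000) == pytest.approx(0.0, abs=1e-12)
        assert calib.evalue(-1e6, 10000) == pytest.approx(10000)

    def test_calibration_reproducible(self, hr_profile):
        model = hr_profile[0]
        c1 = calibrate_evalue(model, n_random=100, length=100, seed=5)
        c2 = calibrate_evalue(model, n_random=100, length=100, seed=5)
        assert c1.gumbel_mu == c2.gumbel_mu
        assert c1.gumbel_lambda == c2.gumbel_lambda

    def test_n_random_floor(self, hr_profile):
        with pytest.raises(ValueError):
            calibrate_evalue(hr_profile[0], n_random=50, length=100, seed=0)

    def test_coverage_boundaries(self):
        def hit(cov):
            h = DomainHit("p", "m", 10.0, (0, int(cov * 100)), (0, 100),
                          protein_length=100)
            h._nodes = 100
            return h
        assert classify_coverage(hit(0.84)) == "long"
        assert classify_coverage(hit(0.85)) == "single_domain"
        assert classify_coverage(hit(1.0)) == "single_domain"

    def test_planted_fixture_discrimination(self, hr_profile):
        model, hr, _, decoys = hr_profile
        from hrsurvey.synth import generate_proteome, single_domain_spec
        planted = generate_proteome([hr], [single_domain_spec()], 30, 1.0, 21,
                                    divergence_range=(0.1, 0.5))
        background = generate_proteome(decoys, [single_domain_spec("DecoyB")],
                                       200, 0.3, 22)
        calib = calibrate_evalue(model, n_random=500, length=200, seed=23)
        db_size = 10000
        planted_ok = sum(
            calib.evalue(viterbi_scan(model, s, score_only=True).bit_score,
                         db_size) < 1e-5 for _, s in planted.proteins)
        decoy_weak = sum(
            (h := viterbi_scan(model, s, score_only=True)) is None
            or calib.evalue(h.bit_score, db_size) > 1e-3
            for _, s in background.proteins)
        assert planted_ok == 30
        assert decoy_weak >= 0.99 * len(background.proteins)

    def test_anchor_weighting_sharpens_discrimination(self, hr_profile):
        """Up-weighting the iron-site anchors should widen the score gap
        between anchor-preserving and anchor-violating homologs."""
        _, hr, _, _ = hr_profile
        from hrsurvey.benchmarks import seed_profile
        weighted = seed_profile(seed=1, anchor_weight=5.0)[0]
        flat = seed_profile(seed=1, anchor_weight=1.0)[0]
        hr_strict, _, _ = make_default_templates(1, anchor_conservation=1.0)
        rng = np.random.default_rng(9)
        gaps_w, gaps_f = [], []
        for pair in range(100):
            keeper = mutate_from_template(hr_strict, 0.4, 7000 + pair)
            violator = list(keeper)
            for pos, res in hr_strict.anchor_positions:
                alts = [a for a in AMINO_ACIDS if a != res]
                violator[pos] = alts[rng.integers(19)]
            violator = "".join(violator)
            for model, acc in ((weighted, gaps_w), (flat, gaps_f)):
                a = viterbi_scan(model, keeper, score_only=True).bit_score
                b = viterbi_scan(model, violator, score_only=True).bit_score
                acc.append(a - b)
        gaps_w, gaps_f = np.array(gaps_w), np.array(gaps_f)
        assert gaps_w.mean() > gaps_f.mean()
        assert (gaps_w > gaps_f).mean() >= 0.95

    def test_sister_family_scores_below_planted(self, hr_profile):
        model, hr, hhe, _ = hr_profile
        below = 0
        for seed in range(100):
            a = viterbi_scan(model, mutate_from_template(hr, 0.4, 40000 + seed),
                             score_only=True).bit_score
            b = viterbi_scan(model, mutate_from_template(hhe, 0.4, 40000 + seed),
                             score_only=True).bit_score
            below += b < a
        assert below >= 95


class TestSerialization:
    def test_round_trip_lossless(self, hr_profile, tmp_path):
        model = hr_profile[0]
        path = tmp_path / "m.phmm"
        write_phmm(model, path)
        back = read_phmm(path)
        assert back.profile_id == model.profile_id
        for a, b in [(back.match_emissions, model.match_emissions),
                     (back.insert_emissions, model.insert_emissions),
                     (back.background, model.background)]:
            assert np.abs(a - b).max() < 1e-12
        for key in model.transitions:
            assert np.abs(back.transitions[key] - model.transitions[key]).max() < 1e-12
        assert back.anchor_nodes == model.anchor_nodes

    def test_bad_format_rejected(self, tmp_path):
        p = tmp_path / "bad.phmm"
        p.write_text("not a profile\n")
        with pytest.raises(ValueError):
            read_phmm(p)


class TestCollectSeed:
    def test_references_collect_themselves(self, templates, scheme):
        hr, _, _ = templates
        refs = [("ref", hr.consensus)]
        db = [("ref_copy", hr.consensus)]
        assert collect_seed(refs, db, scheme=scheme, n_shuffles=50) == db

    def test_impossible_coverage_empty(self, templates, scheme):
        hr, _, _ = templates
        refs = [("ref", hr.consensus)]
        db = [("x", hr.consensus)]
        assert collect_seed(refs, db, coverage_cutoff=1.01, scheme=scheme,
                            n_shuffles=50) == []

    def test_planted_recovery_with_decoys(self, templates, scheme):
        hr, _, _ = templates
        from hrsurvey.synth import generate_proteome, single_domain_spec
        planted = generate_proteome([hr], [single_domain_spec()], 50, 1.0, 31,
                                    divergence_range=(0.1, 0.5),
                                    species_id="pl")
        decoys = generate_proteome([hr], [single_domain_spec()], 500, 0.0, 32,
                                   background_length=(100, 200),
                                   species_id="bg")
        db = planted.proteins + decoys.proteins
        refs = [("ref", hr.consensus)]
        kept = {pid for pid, _ in collect_seed(refs, db, scheme=scheme, seed=33)}
        planted_ids = {pid for pid, _ in planted.proteins}
        assert len(kept & planted_ids) >= 45
        assert not kept - planted_ids
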
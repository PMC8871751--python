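"""Call-matrix loading, ascertainment filtering and outgroup polarization."""

from __future__ import annotations

import numpy as np
import pytest

from patrilinekit.matrix import (
    ANCESTRAL,
    DERIVED,
    HET_ARTIFACT,
    MISSING,
    CallMatrix,
    FilterConfig,
    MatrixError,
    filter_variants,
    load_call_matrix,
    polarize,
    write_call_matrix,
)
from patrilinekit.simulate import SimConfig, simulate

from conftest import make_matrix


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoading:
    def test_empty_site_list_rejected_naming_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("site_id\tS1\tS2\n")
        with pytest.raises(MatrixError, match="empty.tsv"):
            load_call_matrix(p, dialect="matrix")

    def test_missing_symbol_parsed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "site_id\tS1\tS2\tS3\n"
            "v1\t0\t1\t./.\n"
            "v2\t1\t0\t1\n"
        )
        m = load_call_matrix(p, dialect="matrix")
        assert (m.geno == MISSING).sum() == 1
        assert m.geno[m.sample_index("S3"), m.site_index("v1")] == MISSING

    def test_heterozygous_and_unparseable_calls(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("site_id\tS1\tS2\nv1\t0/1\twat\n")
        m = load_call_matrix(p, dialect="matrix")
        assert m.geno[0, 0] == HET_ARTIFACT
        assert m.geno[1, 0] == MISSING  # unparseable becomes missing

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("site_id\tS1\tS1\nv1\t0\t1\n")
        with pytest.raises(MatrixError, match="S1"):
            load_call_matrix(p, dialect="matrix")

    def test_vcf_round_trip_reproduces_states(self, tmp_path, rng):
        # 10 samples x 50 sites with ~5% missingness and depth/quality
        n, m = 10, 50
        geno = (rng.random((n, m)) < 0.3).astype(np.int8)
        geno[rng.random((n, m)) < 0.05] = MISSING
        depth = rng.integers(3, 40, size=(n, m))
        qual = rng.integers(5, 99, size=(n, m))
        matrix = make_matrix(geno, depth=depth, qual=qual, polarized=False)
        path = tmp_path / "round.vcf"
        write_call_matrix(matrix, path, dialect="vcf")
        back = load_call_matrix(path, dialect="vcf")
        assert back.samples == matrix.samples
        assert back.site_ids == matrix.site_ids
        np.testing.assert_array_equal(back.geno, matrix.geno)
        np.testing.assert_array_equal(back.depth, matrix.depth)
        np.testing.assert_array_equal(back.qual, matrix.qual)

    def test_matrix_table_round_trip(self, tmp_path, rng):
        geno = (rng.random((6, 20)) < 0.4).astype(np.int8)
        geno[rng.random((6, 20)) < 0.1] = MISSING
        matrix = make_matrix(geno, polarized=False)
        path = tmp_path / "round.tsv"
        write_call_matrix(matrix, path, dialect="matrix")
        back = load_call_matrix(path, dialect="matrix")
        np.testing.assert_array_equal(back.geno, matrix.geno)
        assert back.site_ids == matrix.site_ids


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _with_meta(matrix: CallMatrix, depth_fill=30, qual_fill=90) -> CallMatrix:
    matrix.depth = np.full(matrix.geno.shape, depth_fill, dtype=np.int32)
    matrix.qual = np.full(matrix.geno.shape, qual_fill, dtype=np.int32)
    return matrix


class TestFiltering:
    def test_low_quality_fraction_rule(self):
        # depth=2 in 2 of 10 samples -> 20% > 10% -> removed
        m = _with_meta(make_matrix(np.zeros((10, 2), dtype=np.int8)))
        m.geno[:, 1] = [0, 1] * 5
        m.geno[0, 0] = 1
        m.depth[0, 0] = 2
        m.depth[1, 0] = 2
        out, report = filter_variants(m, FilterConfig())
        assert out.site_ids == ["v1"]
        assert report.removed == [("v0", ("low_quality_fraction",))]

    def test_call_rate_rule(self):
        m = make_matrix(np.zeros((10, 2), dtype=np.int8))
        m.geno[:, 0] = [1, 0] * 5
        m.geno[:3, 1] = MISSING  # 7/10 called < 75%
        m.geno[3, 1] = 1
        out, report = filter_variants(m, FilterConfig())
        assert report.removed == [("v1", ("call_rate",))]
        assert out.site_ids == ["v0"]

    def test_heterozygous_only_and_reference_error_rules(self):
        m = make_matrix(
            [
                [HET_ARTIFACT, DERIVED, ANCESTRAL],
                [HET_ARTIFACT, DERIVED, DERIVED],
                [HET_ARTIFACT, DERIVED, ANCESTRAL],
                [MISSING, DERIVED, DERIVED],
            ]
        )
        out, report = filter_variants(m, FilterConfig())
        reasons = dict(report.removed)
        assert reasons["v0"] == ("heterozygous_only",)
        assert reasons["v1"] == ("reference_error",)
        assert out.site_ids == ["v2"]

    def test_surviving_het_artifacts_demoted_to_missing(self):
        m = make_matrix(
            [[DERIVED, HET_ARTIFACT], [ANCESTRAL, ANCESTRAL], [ANCESTRAL, DERIVED]]
        )
        out, _ = filter_variants(m, FilterConfig())
        assert (out.geno == HET_ARTIFACT).sum() == 0
        assert out.geno[0, out.site_index("v1")] == MISSING

    def test_multiallelic_rule(self):
        import dataclasses

        m = make_matrix([[0, 1], [1, 0]])
        m.sites[0] = dataclasses.replace(m.sites[0], alt_alleles=("G", "T"))
        out, report = filter_variants(m, FilterConfig())
        assert dict(report.removed)["v0"] == ("multiallelic",)

    def test_outgroup_excluded_from_reference_error_rule(self):
        # all ingroup derived but outgroup ancestral: still a reference error
        # by the ingroup-only definition (the reference is the singleton)
        m = make_matrix([[1, 1], [1, 0], [0, 0]], outgroup="S2")
        _, report = filter_variants(m, FilterConfig())
        assert dict(report.removed)["v0"] == ("reference_error",)

    def test_brute_force_oracle_on_planted_violations(self, rng):
        """Removed-site set equals an independent per-rule scan (20x100)."""
        n, m = 20, 100
        geno = (rng.random((n, m)) < 0.35).astype(np.int8)
        # keep every column honestly polymorphic to start with
        geno[0, :] = 0
        geno[1, :] = 1
        matrix = _with_meta(make_matrix(geno, polarized=False))
        # plant violations of each rule
        matrix.depth[:4, 3] = 1                    # 20% low depth
        matrix.qual[:3, 7] = 2                     # 15% low GQ
        matrix.geno[:6, 11] = MISSING              # 70% call rate
        matrix.geno[:, 17] = HET_ARTIFACT          # het only
        matrix.geno[:, 23] = 1                     # reference error
        import dataclasses

        matrix.sites[29] = dataclasses.replace(
            matrix.sites[29], alt_alleles=("G", "T")
        )
        # random extra noise
        noise = rng.random((n, m)) < 0.03
        matrix.geno[noise] = MISSING
        cfg = FilterConfig()
        _, report = filter_variants(matrix, cfg)

        expected: dict[str, set[str]] = {}
        for j in range(m):
            col = matrix.geno[:, j]
            reasons = set()
            bad = (matrix.depth[:, j] < cfg.min_depth) | (
                matrix.qual[:, j] < cfg.min_quality
            )
            if bad.mean() > cfg.max_low_quality_fraction:
                reasons.add("low_quality_fraction")
            if (col != MISSING).mean() < cfg.min_call_rate:
                reasons.add("call_rate")
            called = col[col != MISSING]
            if called.size and (called == HET_ARTIFACT).all():
                reasons.add("heterozygous_only")
            if len(matrix.sites[j].alt_alleles) > 1:
                reasons.add("multiallelic")
            if called.size and (called == DERIVED).all():
                reasons.add("reference_error")
            if reasons:
                expected[matrix.sites[j].site_id] = reasons
        assert {s: set(r) for s, r in report.removed} == expected

    def test_filtering_contractive_and_idempotent(self, rng):
        geno = (rng.random((12, 40)) < 0.3).astype(np.int8)
        geno[rng.random((12, 40)) < 0.1] = MISSING
        matrix = _with_meta(make_matrix(geno))
        matrix.depth[rng.random((12, 40)) < 0.05] = 1
        once, report = filter_variants(matrix, FilterConfig())
        assert set(once.site_ids) <= set(matrix.site_ids)
        assert len(report.removed) + once.n_sites == matrix.n_sites
        twice, report2 = filter_variants(once, FilterConfig())
        assert twice.site_ids == once.site_ids
        assert report2.removed == []
        np.testing.assert_array_equal(twice.geno, once.geno)


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

class TestPolarization:
    def test_reference_carrying_outgroup_is_identity(self):
        m = make_matrix([[0, 1], [1, 0], [0, 0]], outgroup="S2", polarized=False)
        p = polarize(m, "S2")
        np.testing.assert_array_equal(p.geno, m.geno)
        assert all(s.ancestral_state == "reference" for s in p.sites)

    def test_alternative_outgroup_swaps_exactly_that_site(self):
        m = make_matrix([[0, 1], [1, 0], [1, 0]], outgroup="S2", polarized=False)
        p = polarize(m, "S2")
        # site v0: outgroup derived -> flipped; site v1: untouched
        assert list(p.geno[:, 0]) == [1, 0, 0]
        assert list(p.geno[:, 1]) == [1, 0, 0]
        assert p.sites[0].ancestral_state == "alternative"
        assert p.sites[1].ancestral_state == "reference"

    def test_missing_outgroup_flags_site(self):
        m = make_matrix([[0], [1], [MISSING]], outgroup="S2", polarized=False)
        p = polarize(m, "S2")
        assert p.unpolarized_sites == {"v0"}
        assert p.sites[0].ancestral_state == "unknown"

    def test_absent_outgroup_rejected(self):
        m = make_matrix([[0], [1]])
        with pytest.raises(MatrixError, match="nope"):
            polarize(m, "nope")

    def test_involution_under_outgroup_flip(self, rng):
        geno = (rng.random((8, 15)) < 0.4).astype(np.int8)
        geno[-1, :] = rng.integers(0, 2, 15)
        m = make_matrix(geno, outgroup="S7", polarized=False)
        p1 = polarize(m, "S7")
        flipped = m.copy()
        j = 4
        og = flipped.sample_index("S7")
        flipped.geno[og, j] = 1 - flipped.geno[og, j]
        p2 = polarize(flipped, "S7")
        ingroup = [flipped.sample_index(s) for s in flipped.ingroup_samples]
        for col in range(m.n_sites):
            a = p1.geno[ingroup, col]
            b = p2.geno[ingroup, col]
            if col == j:
                assert (a == 1 - b).all()
            else:
                np.testing.assert_array_equal(a, b)

    def test_polarization_recovers_simulated_ancestral_states(self):
        """With an error-free outgroup, every true ancestral state is recovered."""
        truth = simulate(SimConfig(generations=4, founders=3, mu=0.5, sites=150, seed=5))
        raw = truth.true_matrix.copy()
        raw.polarized = False
        # re-express a random half of the sites with the derived allele as REF
        flip_rng = np.random.default_rng(99)
        flipped = set()
        for i in range(raw.n_sites):
            if flip_rng.random() < 0.5:
                col = raw.geno[:, i]
                raw.geno[:, i] = np.where(col == 0, 1, np.where(col == 1, 0, col))
                flipped.add(raw.sites[i].site_id)
        p = polarize(raw, "OUTGROUP")
        ingroup = [p.sample_index(s) for s in p.ingroup_samples]
        truth_in = [
            truth.true_matrix.sample_index(s) for s in p.ingroup_samples
        ]
        np.testing.assert_array_equal(
            p.geno[ingroup, :], truth.true_matrix.geno[truth_in, :]
        )
        for site in p.sites:
            expected = "alternative" if site.site_id in flipped else "reference"
            assert site.ancestral_state == expected
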
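"""Splicing-mode classification and categorical enrichment tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from spliceforge.events import (
    categorical_enrichment,
    classify_junction,
    splice_site_types,
)
from spliceforge.genemodel import (
    GeneModel,
    GenomicInterval,
    JunctionRecord,
    catalog_junctions,
    flatten_exons,
)

from conftest import make_transcript, random_gene


def _gene_3exon(with_skip=False):
    exons = [(0, 100), (200, 300), (400, 500)]
    ts = [make_transcript("t1", "g", "c", "+", exons)]
    if with_skip:
        ts.append(make_transcript("t2", "g", "c", "+", [(0, 100), (400, 500)]))
    return GeneModel("g", ts, "noncoding")


def _j(donor, acceptor, strand="+", gene="g"):
    return JunctionRecord(
        f"{gene}:{min(donor, acceptor)}-{max(donor, acceptor)}",
        gene, "c", donor, acceptor, strand, canonical=False,
    )


class TestClassifyJunction:
    def test_annotated_pair_is_canonical(self):
        g = _gene_3exon()
        cat = catalog_junctions(g)
        got = classify_junction(cat[0], g, cat)
        assert got.mode == "canonical"

    def test_exon_skip_is_cassette(self):
        g = _gene_3exon()
        cat = catalog_junctions(g)
        got = classify_junction(_j(99, 400), g, cat)
        assert got.mode == "cassette_skipping"
        assert got.evidence == ["c:200-300"]

    def test_novel_donor_in_exon_is_alt_5ss(self):
        g = _gene_3exon()
        cat = catalog_junctions(g)
        # donor 12 nt inside exon 1, canonical exon-2 acceptor
        got = classify_junction(_j(87, 200), g, cat)
        assert got.mode == "alt_5ss"

    def test_novel_acceptor_is_alt_3ss(self):
        g = _gene_3exon()
        cat = catalog_junctions(g)
        got = classify_junction(_j(99, 215), g, cat)
        assert got.mode == "alt_3ss"

    def test_both_sites_novel_is_complex(self):
        g = _gene_3exon()
        cat = catalog_junctions(g)
        got = classify_junction(_j(87, 215), g, cat)
        assert got.mode == "complex"

    def test_skip_with_shifted_site_is_complex(self):
        g = _gene_3exon()
        cat = catalog_junctions(g)
        # skips exon 2 AND uses a novel donor inside exon 1
        got = classify_junction(_j(87, 400), g, cat)
        assert got.mode == "complex"

    def test_mutually_exclusive_pair(self):
        # t1 uses E2, t2 uses E3; E2/E3 never co-occur
        t1 = make_transcript(
            "t1", "g", "c", "+", [(0, 100), (200, 300), (600, 700)]
        )
        t2 = make_transcript(
            "t2", "g", "c", "+", [(0, 100), (400, 500), (600, 700)]
        )
        g = GeneModel("g", [t1, t2], "noncoding")
        cat = catalog_junctions(g)
        got = classify_junction(_j(99, 600), g, cat)
        assert got.mode == "mutually_exclusive"

    def test_outside_gene_span_raises(self):
        g = _gene_3exon()
        with pytest.raises(ValueError):
            classify_junction(_j(99, 1200), g, catalog_junctions(g))

    def test_minus_strand_alt_sites(self):
        t = make_transcript(
            "t", "g", "c", "-", [(0, 100), (200, 300), (400, 500)]
        )
        g = GeneModel("g", [t], "noncoding")
        cat = catalog_junctions(g)
        # on minus strand the donor of intron (100,200) is position 200
        got = classify_junction(_j(215, 99, "-"), g, cat)
        assert got.mode == "alt_5ss"
        got = classify_junction(_j(200, 87, "-"), g, cat)
        assert got.mode == "alt_3ss"

    def test_exhaustive_placements_match_oracle(self):
        """Every junction placement in 3- and 4-exon genes classifies to
        exactly one mode, agreeing with an independent enumeration."""
        for n_exons, with_skip in [(3, False), (3, True), (4, False), (4, True)]:
            exons = [(i * 200, i * 200 + 100) for i in range(n_exons)]
            ts = [make_transcript("t1", "g", "c", "+", exons)]
            if with_skip:
                ts.append(
                    make_transcript(
                        "t2", "g", "c", "+", [exons[0]] + exons[2:]
                    )
                )
            g = GeneModel("g", ts, "noncoding")
            cat = catalog_junctions(g)
            pairs = {(c.donor, c.acceptor) for c in cat}
            donor_sites = {e[1] - 1 for e in exons[:-1]} | {e[1] - 31 for e in exons[:-1]}
            acceptor_sites = {e[0] for e in exons[1:]} | {e[0] + 31 for e in exons[1:]}
            for d, a in itertools.product(donor_sites, acceptor_sites):
                if a - d - 1 < 50:
                    continue
                got = classify_junction(_j(d, a), g, cat)
                # independent oracle
                donors = {e[1] - 1 for e in exons[:-1]}
                if with_skip:
                    donors |= {exons[0][1] - 1}
                acceptors = {e[0] for e in exons[1:]}
                d_known, a_known = d in donors, a in acceptors
                skipped = [e for e in exons if d < e[0] and e[1] <= a]
                if (d, a) in pairs:
                    want = "canonical"
                elif d_known and a_known:
                    want = "cassette_skipping" if skipped else "complex"
                elif not d_known and not a_known:
                    want = "complex"
                elif skipped:
                    want = "complex"
                else:
                    want = "alt_5ss" if not d_known else "alt_3ss"
                assert got.mode == want, (d, a, got.mode, want)

    def test_canonical_never_alternative_on_random_genes(self, rng):
        for i in range(50):
            g = random_gene(rng, f"G{i}", max_transcripts=5, max_exons=8)
            cat = catalog_junctions(g)
            for j in cat:
                assert classify_junction(j, g, cat).mode == "canonical"


class TestSpliceSiteTypes:
    def _gene(self):
        t = make_transcript(
            "t", "g", "c", "+", [(0, 100), (200, 300), (400, 500)],
            cds=(200, 450),
        )
        return GeneModel("g", [t], "protein_coding")

    def test_utr_to_cds_junction(self):
        g = self._gene()
        bins = flatten_exons(g)
        cat = catalog_junctions(g)
        j = next(c for c in cat if c.donor == 99)
        ann = splice_site_types(j, bins)
        assert ann.donor_exon_type == "five_prime_utr"
        assert ann.acceptor_exon_type in ("cds", "multi_type")

    def test_novel_donor_inside_cds_bin(self):
        g = self._gene()
        bins = flatten_exons(g)
        ann = splice_site_types(_j(250, 400), bins)
        assert ann.donor_exon_type == "cds"

    def test_intronic_site_flagged(self):
        g = self._gene()
        bins = flatten_exons(g)
        ann = splice_site_types(_j(150, 400), bins)
        assert ann.donor_exon_type == "intergenic_intronic"


class TestCategoricalEnrichment:
    def test_balanced_table_no_association(self):
        universe = [f"x{i}" for i in range(40)]
        # 20 diff (10 A, 10 B), 20 nondiff (10 A, 10 B)
        category = {f: ("A" if i % 2 else "B") for i, f in enumerate(universe)}
        diff = universe[:20]
        out = categorical_enrichment(diff, universe, category)
        assert out.loc["A", "odds_ratio"] == pytest.approx(1.0)
        assert out.loc["A", "p"] == pytest.approx(1.0)

    def test_strong_association_or16(self):
        # [20, 5; 5, 20]
        diff = [f"d{i}" for i in range(25)]
        nondiff = [f"n{i}" for i in range(25)]
        category = {}
        for i, f in enumerate(diff):
            category[f] = "A" if i < 20 else "B"
        for i, f in enumerate(nondiff):
            category[f] = "A" if i < 5 else "B"
        out = categorical_enrichment(diff, diff + nondiff, category)
        assert out.loc["A", "odds_ratio"] == pytest.approx(16.0)
        want_p = sps.fisher_exact([[20, 5], [5, 20]])[1]
        assert out.loc["A", "p"] == pytest.approx(want_p)

    def test_haldane_correction_on_zero_cell(self):
        # [0, 30; 15, 55]
        diff = [f"d{i}" for i in range(30)]
        nondiff = [f"n{i}" for i in range(70)]
        category = {f: "B" for f in diff}
        for i, f in enumerate(nondiff):
            category[f] = "A" if i < 15 else "B"
        out = categorical_enrichment(diff, diff + nondiff, category)
        want = (0.5 * 55.5) / (30.5 * 15.5)
        assert out.loc["A", "odds_ratio"] == pytest.approx(want, rel=1e-6)

    def test_chi2_variant_matches_scipy_uncorrected(self):
        diff = [f"d{i}" for i in range(30)]
        nondiff = [f"n{i}" for i in range(30)]
        category = {}
        for i, f in enumerate(diff):
            category[f] = "A" if i < 20 else "B"
        for i, f in enumerate(nondiff):
            category[f] = "A" if i < 10 else "B"
        out = categorical_enrichment(diff, diff + nondiff, category, test="chi2")
        want = sps.chi2_contingency([[20, 10], [10, 20]], correction=False)[1]
        assert out.loc["A", "p"] == pytest.approx(want)

    def test_fisher_p_matches_hypergeometric_oracle_small_tables(self):
        """Two-sided Fisher p equals the sum of hypergeometric point
        probabilities <= the observed one, over tables with N <= 30."""
        def oracle(a, b, c, d):
            n1, n0, k = a + b, c + d, a + c
            rv = sps.hypergeom(n1 + n0, n1, k)
            p_obs = rv.pmf(a)
            lo, hi = max(0, k - n0), min(k, n1)
            return sum(
                rv.pmf(x)
                for x in range(lo, hi + 1)
                if rv.pmf(x) <= p_obs * (1 + 1e-9)
            )

        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            n = int(rng.integers(4, 31))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n + 1 - a))
            c = int(rng.integers(0, n + 1 - a - b))
            d = n - a - b - c
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            got = sps.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(oracle(a, b, c, d), rel=1e-8)
            checked += 1
        assert checked > 100

    def test_fewer_than_two_labels_raises(self):
        with pytest.raises(ValueError):
            categorical_enrichment(["a"], ["a", "b"], {"a": "X", "b": "X"})
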
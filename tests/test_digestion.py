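import random

import pytest
import yaml

from collapep import (
    ProteinChain,
    compile_rules,
    cleavage_sites,
    default_rules,
    degree_of_hydrolysis,
    digest,
    length_distribution,
    rank_enzyme_combinations,
)
from collapep.digestion import DigestError, RuleError

from oracles import brute_cleavage_sites

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestCompileRules:
    def test_yaml_roundtrip(self, tmp_path):
        doc = {"trypsin": {"ec": "3.4.21.4", "specs": [{"p1": "KR"}], "exceptions": [{"p1prime": "P"}]}}
        p = tmp_path / "rules.yaml"
        p.write_text(yaml.safe_dump(doc))
        rule = compile_rules(p)["trypsin"]
        assert rule.ec_number == "3.4.21.4"
        assert rule.cleaves("AKG", 1)
        assert not rule.cleaves("AKP", 1)

    def test_empty_spec_list_rejected(self):
        with pytest.raises(RuleError, match="empty spec"):
            compile_rules({"e": {"specs": []}})

    def test_spec_with_no_positions_rejected(self):
        with pytest.raises(RuleError):
            compile_rules({"e": {"specs": [{}]}})

    def test_invalid_residue_named(self):
        with pytest.raises(RuleError, match="e1"):
            compile_rules({"e1": {"specs": [{"p1": "KZ"}]}})

    def test_bundled_table_has_study_enzymes(self):
        table = default_rules()
        for name in ("papain", "ficin", "stem bromelain", "calpain 2",
                     "pancreatic elastase", "trypsin", "chymotrypsin A"):
            assert name in table, name


class TestCleavageSites:
    def test_no_match(self, trypsin_rule):
        chain = ProteinChain(id="c", residues="GAPGAP")
        assert cleavage_sites(chain, trypsin_rule) == []

    def test_trypsin_like_sites(self, trypsin_rule):
        # after K (bond 1) and R (bond 2); K before P (bond 6) is protected
        chain = ProteinChain(id="c", residues="AKRGFPK")
        assert cleavage_sites(chain, trypsin_rule) == [1, 2]

    def test_x_blocks_cleavage(self, trypsin_rule):
        assert cleavage_sites(ProteinChain(id="c", residues="XXXX"), trypsin_rule) == []
        # the K|X bond is adjacent to the unknown residue and stays intact
        assert cleavage_sites(ProteinChain(id="c", residues="AKXG"), trypsin_rule) == []
        assert cleavage_sites(ProteinChain(id="c", residues="AKGX"), trypsin_rule) == [1]

    def test_untrimmed_chain_rejected(self, trypsin_rule):
        chain = ProteinChain(id="c", residues="MAKRG", signal_end=1)
        with pytest.raises(DigestError, match="trim"):
            cleavage_sites(chain, trypsin_rule)

    def test_oracle_equivalence_on_random_chains_and_rules(self):
        """Site finder equals a brute-force per-bond evaluator (1000 cases)."""
        rng = random.Random(20240917)
        positions = ("p2", "p1", "p1prime", "p2prime")
        for _ in range(1000):
            seq = "".join(rng.choice(AA + "X") for _ in range(rng.randint(2, 30)))
            specs = []
            for _ in range(rng.randint(1, 3)):
                spec = {p: None for p in positions}
                for p in rng.sample(positions, rng.randint(1, 3)):
                    spec[p] = set(rng.sample(AA, rng.randint(1, 8)))
                specs.append(spec)
            exceptions = []
            if rng.random() < 0.5:
                exc = {p: None for p in positions}
                exc[rng.choice(positions)] = set(rng.sample(AA, rng.randint(1, 5)))
                exceptions.append(exc)
            rule = compile_rules(
                {
                    "r": {
                        "specs": [
                            {p: "".join(sorted(s)) for p, s in spec.items() if s}
                            for spec in specs
                        ],
                        "exceptions": [
                            {p: "".join(sorted(s)) for p, s in exc.items() if s}
                            for exc in exceptions
                        ],
                    }
                }
            )["r"]
            chain = ProteinChain(id="c", residues=seq)
            assert cleavage_sites(chain, rule) == brute_cleavage_sites(seq, specs, exceptions)


class TestDigest:
    def test_fragments_and_counts(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="AKRGFPK"), [trypsin_rule])
        assert [f[0] for f in r.fragments] == ["AK", "R", "GFPK"]
        assert r.fragments[2] == ("GFPK", 4, 7)  # 1-based inclusive
        assert (r.d, r.D) == (2, 6)

    def test_zero_sites_gives_whole_chain(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="GAPGAP"), [trypsin_rule])
        assert [f[0] for f in r.fragments] == ["GAPGAP"]

    def test_empty_rule_list_rejected(self):
        with pytest.raises(DigestError):
            digest(ProteinChain(id="c", residues="GAP"), [])

    def test_reconstruction_and_fragment_count_invariants(self, trypsin_rule, glu_c_rule):
        rng = random.Random(7)
        for _ in range(200):
            seq = "".join(rng.choice(AA) for _ in range(rng.randint(2, 60)))
            r = digest(ProteinChain(id="c", residues=seq), [trypsin_rule, glu_c_rule])
            assert "".join(f[0] for f in r.fragments) == seq
            assert len(r.fragments) == r.d + 1

    def test_adding_enzyme_never_removes_sites(self, trypsin_rule, glu_c_rule):
        rng = random.Random(11)
        for _ in range(100):
            seq = "".join(rng.choice(AA) for _ in range(30))
            chain = ProteinChain(id="c", residues=seq)
            single = set(digest(chain, [trypsin_rule]).sites)
            both = set(digest(chain, [trypsin_rule, glu_c_rule]).sites)
            assert single <= both


class TestDegreeOfHydrolysis:
    def test_single_chain(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="AKRGFPK"), [trypsin_rule])
        assert degree_of_hydrolysis([r]) == pytest.approx(2 / 6 * 100, abs=1e-3)

    def test_zero_sites_is_zero(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="GAPGAP"), [trypsin_rule])
        assert degree_of_hydrolysis([r]) == 0.0

    def test_copy_weighted_mean(self):
        # DH 30% on the doubled chain, 60% on the single-copy chain -> 40%
        from collapep.digestion import DigestResult

        r1 = DigestResult("a1", tuple(range(3)), 10, ((".", 1, 1),) * 4, ("e",))
        r2 = DigestResult("a2", tuple(range(6)), 10, ((".", 1, 1),) * 7, ("e",))
        got = degree_of_hydrolysis([r1, r2], {"a1": 2, "a2": 1})
        assert got == pytest.approx(40.0)

    def test_single_residue_chain_rejected(self):
        from collapep.digestion import DigestResult

        r = DigestResult("c", (), 0, (("A", 1, 1),), ("e",))
        with pytest.raises(DigestError):
            degree_of_hydrolysis([r])


class TestLengthDistribution:
    def test_direct_count(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="AKRGFPK"), [trypsin_rule])
        assert length_distribution(r) == {"1": 1, "2": 1, "4": 1}

    def test_intact_long_chain(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="GAPGAPG"), [trypsin_rule])
        assert length_distribution(r) == {">=6": 1}

    def test_distinct_sequences_collapse_duplicates(self, trypsin_rule):
        r = digest(ProteinChain(id="c", residues="AKAKGG"), [trypsin_rule])
        assert [f[0] for f in r.fragments] == ["AK", "AK", "GG"]
        assert length_distribution(r) == {"2": 2}
        assert sum(length_distribution(r).values()) == len(r.distinct_sequences())


class TestCombinatorialSearch:
    def test_ranks_by_score_then_dh_then_name(self, small_db):
        table = compile_rules(
            {
                "after-K": {"specs": [{"p1": "K"}]},
                "after-V": {"specs": [{"p1": "V"}]},
                "after-G": {"specs": [{"p1": "G"}]},
            }
        )
        chains = [ProteinChain(id="c", residues="AKAVYG")]
        from collapep import release_frequency, weighted_profile

        def score(results):
            return weighted_profile(
                [release_frequency(r, small_db, "ACE inhibitor") for r in results]
            )

        ranked = rank_enzyme_combinations(chains, table, score, sizes=(2,))
        combos = [r[0] for r in ranked]
        assert len(combos) == 3
        # after-K + after-G releases AK and (AVYG); after-K+after-V releases AK, AV
        assert combos[0] == ("after-K", "after-V")
        assert ranked[0][1] > ranked[-1][1] or ranked[0][2] >= ranked[-1][2]
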
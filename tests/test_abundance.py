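"""Taxon tables, absolute abundance, shared species and fold-change calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from viamet import (
    InvalidInputError,
    MicrobiotaLoad,
    SampleRecord,
    absolute_abundance,
    classify_response,
    host_read_fraction,
    read_taxon_table,
    shared_species,
    species_fold_change,
    strip_spikeins,
    taxon_table_from_frame,
    wilcoxon_signed_rank,
)
from viamet.abundance import FoldChangeResult, ReadAccounting, TaxonTable, species_token


def lineage(species, phylum="Firmicutes"):
    genus = species.split()[0]
    return (
        f"k__Bacteria|p__{phylum}|c__C|o__O|f__F|g__{genus}|s__"
        + species.replace(" ", "_")
    )


class TestTaxonTableIO:
    def test_percent_table_becomes_fractions(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "clade_name\tS1\n"
            f"{lineage('Genus one')}\t60.0\n"
            f"{lineage('Genus two')}\t40.0\n"
        )
        t = read_taxon_table(p)
        assert t.data["S1"].tolist() == pytest.approx([0.6, 0.4])

    def test_fraction_table_unchanged(self):
        df = pd.DataFrame(
            {"S1": [0.6, 0.4]}, index=[lineage("A a"), lineage("B b")]
        )
        t = taxon_table_from_frame(df)
        assert t.data["S1"].tolist() == pytest.approx([0.6, 0.4])

    def test_duplicate_lineage_rejected(self):
        df = pd.DataFrame({"S1": [0.5, 0.5]}, index=[lineage("A a"), lineage("A a")])
        with pytest.raises(InvalidInputError):
            taxon_table_from_frame(df)

    def test_zero_sample_warns(self):
        df = pd.DataFrame(
            {"S1": [0.6, 0.4], "S2": [0.0, 0.0]},
            index=[lineage("A a"), lineage("B b")],
        )
        with pytest.warns(UserWarning, match="zero total"):
            taxon_table_from_frame(df)

    def test_species_rank_filter(self):
        df = pd.DataFrame(
            {"S1": [1.0, 0.6, 0.4]},
            index=["k__Bacteria", lineage("A a"), lineage("B b")],
        )
        t = taxon_table_from_frame(df)
        sp = t.species_level()
        assert sp.data.shape[0] == 2
        assert sp.data["S1"].sum() == pytest.approx(1.0)


class TestStripSpikeins:
    def test_removal_renormalizes(self):
        df = pd.DataFrame(
            {"S1": [0.5, 0.3, 0.2]},
            index=[lineage("Spike sp"), lineage("A a"), lineage("B b")],
        )
        t, removed = strip_spikeins(taxon_table_from_frame(df), ["Spike sp"])
        assert t.data["S1"].tolist() == pytest.approx([0.6, 0.4])
        assert removed["S1"] == pytest.approx(0.5)

    def test_absent_spike_warns_table_unchanged(self):
        df = pd.DataFrame({"S1": [0.6, 0.4]}, index=[lineage("A a"), lineage("B b")])
        with pytest.warns(UserWarning, match="not detected"):
            t, removed = strip_spikeins(taxon_table_from_frame(df), ["Ghost strain"])
        assert t.data.equals(taxon_table_from_frame(df).data)
        assert removed["S1"] == 0.0

    def test_all_spike_sample_rejected(self):
        df = pd.DataFrame({"S1": [1.0]}, index=[lineage("Spike sp")])
        with pytest.raises(InvalidInputError):
            strip_spikeins(taxon_table_from_frame(df), ["Spike sp"])

    def test_name_normalization(self):
        assert species_token("s__Escherichia_coli") == "Escherichia coli"
        assert species_token(lineage("Escherichia coli")) == "Escherichia coli"
        assert species_token("Escherichia  coli") == "Escherichia coli"


class TestHostReadFraction:
    def test_basic(self):
        assert host_read_fraction(ReadAccounting("s", 845, 155)) == pytest.approx(0.845)
        assert host_read_fraction(ReadAccounting("s", 0, 100)) == 0.0
        assert host_read_fraction(ReadAccounting("s", 10, 10)) == 0.5

    def test_spikein_reads_excluded(self):
        # 10 host, 30 microbial of which 20 are spike-in -> 10/(10+10)
        assert host_read_fraction(ReadAccounting("s", 10, 30, 20)) == 0.5

    def test_scale_invariance(self):
        a = host_read_fraction(ReadAccounting("s", 84, 16, 4))
        b = host_read_fraction(ReadAccounting("s", 840, 160, 40))
        assert a == pytest.approx(b)

    def test_zero_denominator(self):
        from viamet import UndefinedRatioError

        with pytest.raises(UndefinedRatioError):
            host_read_fraction(ReadAccounting("s", 0, 5, 5))


class TestAbsoluteAbundance:
    def make(self, comp, loads_cpu):
        n_rows = len(next(iter(comp.values())))
        idx = [lineage(f"Sp {i}") for i in range(n_rows)]
        t = taxon_table_from_frame(pd.DataFrame({s: c for s, c in comp.items()}, index=idx))
        loads = {s: MicrobiotaLoad(s, v, "per_mL") for s, v in loads_cpu.items()}
        return t, loads

    def test_scaling_and_column_sums(self):
        t, loads = self.make({"S1": [0.5, 0.5], "S2": [0.5, 0.5]}, {"S1": 1e9, "S2": 2e9})
        abs_t = absolute_abundance(t, loads)
        assert abs_t.data["S1"].tolist() == pytest.approx([5e8, 5e8])
        # identical composition, doubled load -> doubled column
        assert abs_t.data["S2"].tolist() == pytest.approx([1e9, 1e9])
        for s in ("S1", "S2"):
            assert abs_t.data[s].sum() == pytest.approx(
                loads[s].copies_per_unit, rel=1e-9
            )

    def test_zero_stays_zero(self):
        t, loads = self.make({"S1": [1.0, 0.0]}, {"S1": 7e8})
        assert absolute_abundance(t, loads).data["S1"].iloc[1] == 0.0

    def test_missing_load_names_sample(self):
        t, loads = self.make({"S1": [1.0], "S2": [1.0]}, {"S1": 1e9})
        with pytest.raises(InvalidInputError, match="S2"):
            absolute_abundance(t, loads)


def records_grid(hosts, groups, reps, sample_type="saliva"):
    return [
        SampleRecord(f"{h}_{sample_type}_{g}_r{r}", h, sample_type, g, r)
        for h in hosts
        for g in groups
        for r in range(1, reps + 1)
    ]


class TestSharedSpecies:
    def build_table(self, presence: dict[str, set[str]], records):
        """presence: host -> set of species present in its control samples."""
        species = sorted(set().union(*presence.values()))
        cols = {}
        for r in records:
            vals = []
            for sp in species:
                vals.append(1.0 if sp in presence[r.host_id] else 0.0)
            cols[r.sample_id] = vals
        df = pd.DataFrame(cols, index=[lineage(s) for s in species])
        return taxon_table_from_frame(df)

    def test_intersection(self):
        recs = records_grid(["H1", "H2", "H3"], ["control"], 1)
        t = self.build_table(
            {"H1": {"Aa a", "Bb b"}, "H2": {"Bb b", "Cc c"}, "H3": {"Bb b"}}, recs
        )
        assert shared_species(t, recs, "saliva") == ["Bb b"]

    def test_disjoint_hosts_empty(self):
        recs = records_grid(["H1", "H2"], ["control"], 1)
        t = self.build_table({"H1": {"Aa a"}, "H2": {"Bb b"}}, recs)
        assert shared_species(t, recs, "saliva") == []

    def test_single_host_rejected(self):
        recs = records_grid(["H1"], ["control"], 2)
        t = self.build_table({"H1": {"Aa a"}}, recs)
        with pytest.raises(InvalidInputError):
            shared_species(t, recs, "saliva")

    def test_simulated_core_recovered_exactly(self):
        from viamet import generate_study, strip_spikeins
        from viamet.simulate import SPIKE_STRAINS

        config = {
            "sample_types": ["saliva"],
            "saliva": {
                "n_core_species": 50,
                "n_private_species": 5,
                "host_read_fraction": 0.01,
                "weight_sigma": 1.0,
            },
        }
        study = generate_study(config, seed=3)
        table = taxon_table_from_frame(study.taxon_tables["saliva"])
        stripped, _ = strip_spikeins(table, [s["name"] for s in SPIKE_STRAINS])
        got = shared_species(stripped, study.sample_records(), "saliva")
        core = sorted(
            study.truth_taxa.query("core")["taxon"].unique()
        )
        assert got == core
        assert len(got) == 50


class TestWilcoxon:
    def test_all_equal_degenerate(self):
        res = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert res.degenerate and res.p_value == 1.0

    @pytest.mark.parametrize("n, expected", [(5, 2 / 32), (6, 2 / 64)])
    def test_one_sided_sign_runs(self, n, expected):
        res = wilcoxon_signed_rank([(i + 1.0, 0.0) for i in range(n)])
        assert res.p_value == pytest.approx(expected)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(4, 11)
            d = rng.normal(size=n)
            pairs = np.column_stack([d, np.zeros(n)])
            ours = wilcoxon_signed_rank(pairs)
            ref = stats.wilcoxon(d, method="exact", alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_enumeration_oracle_with_ties(self):
        """Independent brute force over all sign vectors, including tied
        absolute differences (integer-valued data)."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(3, 10))
            d = rng.integers(-4, 5, size=n).astype(float)
            d = d[d != 0]
            if d.size == 0:
                continue
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=d.size)
            ]
            dist = np.array(dist, dtype=float)
            p_le = np.mean(dist <= w_obs + 1e-12)
            p_ge = np.mean(dist >= w_obs - 1e-12)
            expected = min(1.0, 2 * min(p_le, p_ge))
            got = wilcoxon_signed_rank(np.column_stack([d, np.zeros(d.size)]))
            assert got.p_value == pytest.approx(expected, rel=1e-12)

    def test_large_n_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, size=30)
        ours = wilcoxon_signed_rank(
            np.column_stack([d, np.zeros(30)]), exact_limit=12
        )
        ref = stats.wilcoxon(d, method="approx", correction=True)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestFoldChange:
    def abs_table(self, values: dict[str, dict[str, float]]):
        """values: species -> sample_id -> absolute abundance."""
        df = pd.DataFrame(values).T
        df.index = [lineage(s) for s in df.index]
        from viamet.abundance import AbsoluteAbundanceTable

        loads = {
            s: MicrobiotaLoad(s, float(df[s].sum()), "per_mL") for s in df.columns
        }
        return AbsoluteAbundanceTable(df, loads)

    def test_identical_values_fold_one(self):
        recs = records_grid(["H1", "H2", "H3"], ["control", "lyPMAxx"], 3)
        vals = {"Aa a": {r.sample_id: 5.0 for r in recs}}
        res = species_fold_change(self.abs_table(vals), recs)
        assert res[0].fold_change == pytest.approx(1.0)
        assert res[0].p_value == 1.0

    def test_tenfold_over_nine_pairs(self):
        recs = records_grid(["H1", "H2", "H3"], ["control", "lyPMAxx"], 3)
        vals = {"Aa a": {}}
        for r in recs:
            vals["Aa a"][r.sample_id] = 10.0 if r.group == "control" else 1.0
        res = species_fold_change(self.abs_table(vals), recs)
        assert res[0].fold_change == pytest.approx(10.0)
        assert res[0].n_pairs == 9
        assert res[0].p_value == pytest.approx(2 / 2**9)  # min attainable, n=9

    def test_zero_treated_uses_pseudocount(self):
        recs = records_grid(["H1", "H2", "H3"], ["control", "lyPMAxx"], 3)
        vals = {"Aa a": {}, "Bb b": {}}
        for r in recs:
            vals["Aa a"][r.sample_id] = 8.0 if r.group == "control" else 0.0
            vals["Bb b"][r.sample_id] = 2.0
        res = {r.species: r for r in species_fold_change(self.abs_table(vals), recs)}
        r = res["Aa a"]
        assert r.pseudocount_used
        assert math.isfinite(r.fold_change)
        assert r.fold_change == pytest.approx(8.0 / 1.0)  # pseudocount = 2/2

    def test_all_zero_not_evaluated(self):
        recs = records_grid(["H1", "H2"], ["control", "lyPMAxx"], 2)
        vals = {"Aa a": {r.sample_id: 0.0 for r in recs},
                "Bb b": {r.sample_id: 1.0 for r in recs}}
        res = {r.species: r for r in species_fold_change(self.abs_table(vals), recs)}
        assert res["Aa a"].response_class == "not_evaluated"

    def test_reciprocal_invariant(self):
        rng = np.random.default_rng(21)
        recs = records_grid(["H1", "H2", "H3"], ["control", "lyPMAxx"], 3)
        vals = {
            f"Sp {i}": {r.sample_id: float(rng.lognormal(10, 1)) for r in recs}
            for i in range(8)
        }
        tbl = self.abs_table(vals)
        fwd = {r.species: r for r in species_fold_change(tbl, recs, "control", "lyPMAxx")}
        rev = {r.species: r for r in species_fold_change(tbl, recs, "lyPMAxx", "control")}
        for sp in fwd:
            assert fwd[sp].fold_change * rev[sp].fold_change == pytest.approx(1.0, rel=1e-12)

    def test_host_mean_pairing_uses_three_pairs(self):
        recs = records_grid(["H1", "H2", "H3"], ["control", "lyPMAxx"], 3)
        vals = {"Aa a": {r.sample_id: 10.0 if r.group == "control" else 1.0 for r in recs}}
        res = species_fold_change(self.abs_table(vals), recs, pairing="host_mean")
        assert res[0].n_pairs == 3
        assert res[0].p_value == pytest.approx(2 / 8)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(2)
        recs = records_grid(["H1", "H2", "H3"], ["control", "lyPMAxx"], 3)
        vals = {
            f"Sp {i}": {
                r.sample_id: float(
                    rng.lognormal(10, 0.1) * (3.0 if r.group == "control" and i < 5 else 1.0)
                )
                for r in recs
            }
            for i in range(10)
        }
        raw = species_fold_change(self.abs_table(vals), recs)
        adj = species_fold_change(self.abs_table(vals), recs, adjust="bh")
        for a, b in zip(raw, adj):
            assert b.p_value >= a.p_value - 1e-12


class TestClassifyResponse:
    def fc(self, fold):
        return FoldChangeResult("X x", 1.0, 1.0, fold, 0.01, "unclassified", False, 9)

    @pytest.mark.parametrize(
        "fold, preset, expected",
        [
            (30.0, "freezing_feces", "responsive"),
            (2.0, "lyPMAxx", "resilient"),
            (2.0, "freezing_saliva", "resilient"),
            (2.0, "freezing_feces", "resilient"),
            (5.0, "freezing_saliva", "intermediate"),
            (5.0, "lyPMAxx", "responsive"),
        ],
    )
    def test_presets(self, fold, preset, expected):
        (res,) = classify_response([self.fc(fold)], preset)
        assert res.response_class == expected

    def test_explicit_thresholds_and_validation(self):
        (res,) = classify_response([self.fc(3.0)], (4.0, 2.5))
        assert res.response_class == "intermediate"
        with pytest.raises(InvalidInputError):
            classify_response([self.fc(3.0)], (2.0, 2.5))
        with pytest.raises(InvalidInputError):
            classify_response([self.fc(3.0)], "no_such_preset")

    def test_nan_fold_stays_not_evaluated(self):
        r = FoldChangeResult("X x", math.nan, math.nan, math.nan, math.nan,
                             "not_evaluated", False, 0)
        (res,) = classify_response([r], "lyPMAxx")
        assert res.response_class == "not_evaluated"
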
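import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import fluxscreen as fs
from fluxscreen.errors import (
    AlignmentError,
    CannotCenterError,
    CannotThresholdError,
    InsufficientReplicatesError,
    InvalidParameterError,
    ParseError,
    UndefinedCorrelationError,
)
from fluxscreen.scoring import (
    ScreenExperiment,
    make_sample_sheet,
    ntc_noise_metric,
    write_gene_table,
)


def _expt(counts: dict, meta_rows=None, mode="in_vitro"):
    counts = pd.DataFrame(counts)
    counts.index.name = "sgrna_id"
    if meta_rows is None:
        meta_rows = [{"sample_id": c, "arm": c, "replicate": 1} for c in counts.columns]
    return ScreenExperiment(counts, make_sample_sheet(meta_rows), mode=mode)


class TestAlignOrLoad:
    def test_exact_match_counting_and_rate(self, small_manifest, tmp_path):
        sg = small_manifest.entries[0]
        reads = [sg.protospacer, sg.protospacer, "A" * len(sg.protospacer)]
        path = tmp_path / "r.fastq"
        path.write_text("".join(f"@r{i}\n{s}\n+\n{'I'*len(s)}\n" for i, s in enumerate(reads)))
        expt = fs.align_or_load_counts(path, small_manifest)
        assert expt.counts.loc[sg.sgrna_id].iloc[0] == 2
        assert expt.meta["alignment_rate"] == pytest.approx(2 / 3)

    def test_single_mismatch_not_counted(self, small_manifest, tmp_path):
        sg = small_manifest.entries[0]
        mutated = ("T" if sg.protospacer[0] != "T" else "G") + sg.protospacer[1:]
        path = tmp_path / "r.fastq"
        path.write_text(f"@r0\n{mutated}\n+\n{'I'*len(mutated)}\n")
        expt = fs.align_or_load_counts(path, small_manifest)
        assert expt.counts.to_numpy().sum() == 0

    def test_malformed_record_reports_index(self, small_manifest, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n")
        with pytest.raises(ParseError) as err:
            fs.align_or_load_counts(path, small_manifest)
        assert err.value.record_index == 1

    def test_counts_tsv_loading(self, small_manifest, tmp_path):
        ids = [e.sgrna_id for e in small_manifest.entries]
        df = pd.DataFrame({"s1": 5, "s2": 7}, index=pd.Index(ids, name="sgrna_id"))
        path = tmp_path / "c.tsv"
        df.to_csv(path, sep="\t")
        expt = fs.align_or_load_counts(path, small_manifest)
        assert expt.counts.equals(df)


class TestTechnicalReplicates:
    def test_identical_duplicates_are_idempotent(self):
        expt = _expt(
            {"a1": [100, 300], "a2": [100, 300]},
            [
                {"sample_id": "a1", "arm": "a", "replicate": 1, "tech_rep": 1},
                {"sample_id": "a2", "arm": "a", "replicate": 1, "tech_rep": 2},
            ],
        )
        out = fs.average_technical_replicates(expt)
        rpm = expt.counts["a1"] / 400 * 1e6
        assert np.allclose(out.counts.iloc[:, 0], rpm)

    def test_depth_normalized_average(self):
        """Totals 1e6 and 2e6 with one sgRNA at 100 and 200 raw reads both
        map to 100 reads per million, so the average is 100."""
        expt = _expt(
            {"a1": [100, 1_000_000 - 100], "a2": [200, 2_000_000 - 200]},
            [
                {"sample_id": "a1", "arm": "a", "replicate": 1, "tech_rep": 1},
                {"sample_id": "a2", "arm": "a", "replicate": 1, "tech_rep": 2},
            ],
        )
        out = fs.average_technical_replicates(expt)
        assert out.counts.iloc[0, 0] == pytest.approx(100.0)

    def test_single_replicate_passes_through(self):
        expt = _expt({"a": [5, 10]})
        out = fs.average_technical_replicates(expt)
        assert out.counts["a"].tolist() == [5, 10]


class TestFilterAndPseudocount:
    def _scaffold(self, t, c, min_count, filler=10_000, pseudocount=10):
        # a filler sgRNA equalizes totals so depth-matching is the identity
        expt = _expt({"t": [t, filler - t], "c": [c, filler - c]})
        return fs.filter_and_pseudocount(expt, ("t", "c"), min_count, pseudocount)

    @pytest.mark.parametrize(
        "t, c, min_count, kept",
        [
            (150, 3, 100, True),  # one condition above the cut-off suffices
            (99, 99, 100, False),  # boundary: both below
            (100, 0, 100, True),  # boundary: >= passes
            (30, 0, 25, True),  # lowered in vivo cut-off
            (24, 24, 25, False),
        ],
    )
    def test_min_count_rule(self, t, c, min_count, kept):
        scaffold = self._scaffold(t, c, min_count)
        assert bool(scaffold["pass_filter"].iloc[0]) is kept

    def test_pseudocount_added_to_retained_only(self):
        scaffold = self._scaffold(150, 3, 100)
        assert scaffold["treated"].iloc[0] == pytest.approx(160.0)
        assert scaffold["control"].iloc[0] == pytest.approx(13.0)

    def test_negative_min_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            self._scaffold(10, 10, -1)


class TestSgrnaPhenotype:
    def _scaffold(self, treated, control):
        idx = [f"sg{i}" for i in range(len(treated))]
        df = pd.DataFrame(
            {"treated": treated, "control": control, "pass_filter": True},
            index=pd.Index(idx, name="sgrna_id"),
        )
        return df

    def test_ratio_at_ntc_median_gives_zero(self):
        scaffold = self._scaffold([200, 100, 100], [100, 50, 50])
        out = fs.sgrna_phenotype(scaffold, ["sg1", "sg2"], doublings=4)
        assert out["rho"].iloc[0] == 0.0

    def test_formula_and_in_vivo_variant(self):
        """Depth-matched counts 400 vs 100 with a zero NTC median: rho is
        log2(4)/D = 0.5 at D = 4 in vitro, and 2.0 in vivo (no doubling
        normalization)."""
        scaffold = self._scaffold([400, 100, 100], [100, 100, 100])
        vitro = fs.sgrna_phenotype(scaffold, ["sg1", "sg2"], doublings=4)
        assert vitro["rho"].iloc[0] == pytest.approx(0.5)
        vivo = fs.sgrna_phenotype(scaffold, ["sg1", "sg2"], doublings=0, mode="in_vivo")
        assert vivo["rho"].iloc[0] == pytest.approx(2.0)

    def test_ntc_median_exactly_zero(self, rng):
        treated = rng.integers(50, 5000, 200).astype(float)
        control = rng.integers(50, 5000, 200).astype(float)
        scaffold = self._scaffold(treated, control)
        ntc = [f"sg{i}" for i in range(0, 200, 3)]
        out = fs.sgrna_phenotype(scaffold, ntc, doublings=6)
        assert np.median(out["rho"].loc[ntc]) == 0.0

    def test_empty_ntc_set_raises(self):
        scaffold = self._scaffold([1, 2], [1, 2])
        with pytest.raises(CannotCenterError):
            fs.sgrna_phenotype(scaffold, [], doublings=4)


class TestGeneScore:
    def test_constant_vector_is_its_own_score(self):
        row = fs.gene_score([0.3] * 10, np.linspace(-0.1, 0.1, 30))
        assert row["phenotype_score"] == pytest.approx(0.3)

    def test_top_seven_selection_matches_brute_force(self):
        rhos = [-1.0, -0.9, -0.8, -0.7, -0.6, -0.5, -0.4, 0.1, 0.2, 0.3]
        best = max(
            itertools.combinations(rhos, 7), key=lambda s: sum(abs(v) for v in s)
        )
        assert np.mean(best) == pytest.approx(-0.7)
        assert fs.top_k_signed_mean(rhos, 7) == pytest.approx(-0.7)

    def test_mannwhitney_enumeration_example(self):
        """3 vs 4 with the test group holding the top ranks: only 2 of the
        35 rank configurations are as extreme, so p = 2/35."""
        assert fs.mannwhitney_p([5, 6, 7], [1, 2, 3, 4]) == pytest.approx(2 / 35)

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=11)
        ours = fs.mannwhitney_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_too_few_sgrnas_marks_unscored(self):
        row = fs.gene_score([0.1, 0.2], [0.0] * 20, min_sgrnas=5)
        assert not row["scored"] and math.isnan(row["screen_score"])

    def test_screen_score_sign_and_floor(self):
        row = fs.gene_score([-2.0] * 10, np.zeros(30), p_floor=1e-16)
        assert row["screen_score"] < 0
        assert abs(row["screen_score"]) <= abs(row["phenotype_score"]) * 16

    @given(st.integers(0, 2**31 - 1))
    def test_top_k_matches_brute_force_property(self, seed):
        vals = np.random.default_rng(seed).normal(size=10)
        best = max(
            itertools.combinations(vals, 7), key=lambda s: sum(abs(v) for v in s)
        )
        assert fs.top_k_signed_mean(vals, 7) == pytest.approx(float(np.mean(best)))


@pytest.fixture(scope="module")
def scored(screen_manifest, screen_pseudogenes):
    spiked = {screen_manifest.genes[0]: -0.5}
    design = fs.ScreenDesign(
        arms=[fs.Arm("control", 8.0, 0.0), fs.Arm("treated", 8.0, 1.0)],
        n_replicates=1,
        reads_per_sgrna=500,
    )
    expt = fs.simulate_screen(
        screen_manifest, fs.ScreenTruth(effects=spiked), design, seed=21
    )
    table = fs.score_screen(
        expt, screen_manifest, screen_pseudogenes, ("treated_rep1", "control_rep1")
    )
    return spiked, table


class TestScoreScreenPipeline:

    def test_spiked_gene_has_most_negative_score(self, scored):
        spiked, table = scored
        idx = table["screen_score"].idxmin()
        assert table.loc[idx, "gene"] in spiked

    def test_pseudogenes_scored_alongside_genes(self, scored):
        _, table = scored
        assert table["is_pseudogene"].sum() == 489
        assert (~table["is_pseudogene"]).sum() == 489

    def test_depth_rescaling_invariance_without_pseudocount(
        self, small_manifest
    ):
        design = fs.ScreenDesign(arms=[fs.Arm("a", 4.0), fs.Arm("b", 4.0, 0.0)], n_replicates=1)
        expt = fs.simulate_screen(small_manifest, fs.ScreenTruth(), design, seed=3)
        pgs = fs.make_pseudogenes(small_manifest, 5, size=10, seed=4)
        params = fs.ScoringParams(min_count=5, pseudocount=0)
        base = fs.score_screen(expt, small_manifest, pgs, ("a_rep1", "b_rep1"), params)
        scaled = ScreenExperiment(
            expt.counts.assign(a_rep1=expt.counts["a_rep1"] * 7),
            expt.samples,
        )
        rescored = fs.score_screen(scaled, small_manifest, pgs, ("a_rep1", "b_rep1"), params)
        assert np.allclose(
            base["screen_score"].fillna(0), rescored["screen_score"].fillna(0)
        )


class TestReplicatesAndHits:
    def _table(self, genes, ss, pseudo_flags):
        n = len(genes)
        return pd.DataFrame(
            {
                "gene": genes,
                "tss": ["primary"] * n,
                "is_pseudogene": pseudo_flags,
                "phenotype_score": ss,
                "p_value": [0.01] * n,
                "screen_score": ss,
                "n_sgrnas": [10] * n,
                "scored": [True] * n,
                "class": ["none"] * n,
            }
        )

    def test_average_replicates_mean_and_passthrough(self):
        t1 = self._table(["g1", "p1"], [0.4, 0.0], [False, True])
        t2 = self._table(["g1", "p1"], [0.6, 0.0], [False, True])
        avg = fs.average_replicates([t1, t2])
        assert avg["screen_score"].iloc[0] == pytest.approx(0.5)
        same = fs.average_replicates([t1, t1, t1])
        assert np.allclose(same["screen_score"], t1["screen_score"])

    def test_average_replicates_mismatched_universe(self):
        t1 = self._table(["g1"], [0.4], [False])
        t2 = self._table(["g2"], [0.4], [False])
        with pytest.raises(AlignmentError):
            fs.average_replicates([t1, t2])

    def test_degenerate_null_flags_any_nonzero_gene(self):
        table = self._table(
            ["g1", "g2", "p1", "p2"], [0.2, -0.3, 0.0, 0.0], [False, False, True, True]
        )
        out = fs.call_hits(table)
        assert out.set_index("gene")["class"].to_dict() == {
            "g1": "enriched",
            "g2": "depleted",
            "p1": "none",
            "p2": "none",
        }

    def test_knockdown_style_cutoffs(self):
        """Pseudogene extremes (0.49, -0.40) reproduce the knock-down screen
        cut-offs: significance requires >0.49 or <-0.40."""
        table = self._table(
            ["g_up", "g_dn", "g_mid", "p1", "p2"],
            [0.50, -0.41, 0.45, 0.49, -0.40],
            [False, False, False, True, True],
        )
        out = fs.call_hits(table)
        classes = out.set_index("gene")["class"]
        assert classes["g_up"] == "enriched"
        assert classes["g_dn"] == "depleted"
        assert classes["g_mid"] == "none"

    def test_untreated_arm_exclusion_rule(self):
        """A hit with untreated score -0.2 is discarded at -0.3 in the test
        condition but kept when strongly resistant (+1.8)."""
        untreated = self._table(["g1", "g2"], [-0.2, -0.2], [False, False])
        for score, expected in [(-0.3, "none"), (1.8, "enriched")]:
            table = self._table(
                ["g1", "g2", "p1"], [score, 0.0, 0.0], [False, False, True]
            )
            out = fs.call_hits(table, untreated=untreated)
            assert out.set_index("gene")["class"]["g1"] == expected

    def test_no_pseudogenes_raises(self):
        table = self._table(["g1"], [0.5], [False])
        with pytest.raises(CannotThresholdError):
            fs.call_hits(table)

    def test_normalize_to_most_depleted(self):
        table = self._table(["a", "b", "c"], [-2.0, -1.0, 0.5], [False] * 3)
        out = fs.normalize_to_most_depleted(table)
        assert out["screen_score"].tolist() == pytest.approx([-1.0, -0.5, 0.25])
        again = fs.normalize_to_most_depleted(out)
        assert again["screen_score"].tolist() == pytest.approx([-1.0, -0.5, 0.25])

    def test_normalize_without_negatives_is_noop(self):
        table = self._table(["a"], [0.5], [False])
        out = fs.normalize_to_most_depleted(table)
        assert out["screen_score"].tolist() == [0.5]
        assert out.attrs["normalized"] is False

    def test_condition_correlation_identity_and_inverse(self):
        genes = [f"g{i}" for i in range(10)]
        ss = np.linspace(-1, 1, 10)
        t = self._table(genes, ss, [False] * 10)
        t["class"] = "depleted"
        t_inv = t.copy()
        t_inv["screen_score"] = -t_inv["screen_score"]
        r, p, used = fs.condition_correlation({"a": t, "b": t.copy(), "c": t_inv})
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert len(used) == 10

    def test_condition_correlation_matches_hand_computation(self, rng):
        genes = [f"g{i}" for i in range(10)]
        x, y = rng.normal(size=10), rng.normal(size=10)
        ta, tb = self._table(genes, x, [False] * 10), self._table(genes, y, [False] * 10)
        ta["class"] = tb["class"] = "depleted"
        r, _, _ = fs.condition_correlation({"a": ta, "b": tb})
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        hand = cov / (x.std() * y.std())
        assert r.loc["a", "b"] == pytest.approx(hand)

    def test_condition_correlation_needs_three_genes(self):
        t = self._table(["g1", "g2"], [0.1, 0.2], [False, False])
        with pytest.raises(UndefinedCorrelationError):
            fs.condition_correlation({"a": t, "b": t.copy()})

    def test_write_gene_table_round_trip(self, tmp_path):
        table = self._table(["g1", "p1"], [0.4, 0.0], [False, True])
        path = tmp_path / "scores.tsv"
        write_gene_table(table, path)
        loaded = pd.read_csv(path, sep="\t")
        assert loaded["gene"].tolist() == ["g1", "p1"]


class TestInVivo:
    def test_noise_metric_counts_out_of_band_ntcs(self):
        """728 NTCs at the median plus one at 1000 and one at 1: exactly two
        sgRNAs are outside one log2 of the median."""
        ids = [f"NTC_{i}" for i in range(730)]
        counts = pd.Series(100.0, index=ids)
        counts.iloc[0], counts.iloc[1] = 1000.0, 1.0
        assert ntc_noise_metric(counts, ids) == 2

    def test_uniform_counts_give_zero_metric(self):
        ids = [f"NTC_{i}" for i in range(10)]
        assert ntc_noise_metric(pd.Series(100.0, index=ids), ids) == 0

    @pytest.fixture
    def qc_manifest(self):
        return fs.build_manifest({"SLC": 3}, two_tss_genes=0, n_ntc=200, seed=13)

    @pytest.fixture
    def tumour_expt(self, qc_manifest):
        ids = [e.sgrna_id for e in qc_manifest.entries]
        ntc = qc_manifest.ntc_ids
        cols, rows = {}, []
        for j, metric in enumerate([0, 1, 2, 3, 50, 60]):
            col = pd.Series(100.0, index=ids)
            col.loc[ntc[:metric]] = 1000.0
            sid = f"tumour{j}"
            cols[sid] = col
            rows.append({"sample_id": sid, "arm": "tumour", "replicate": j})
        counts = pd.DataFrame(cols)
        counts.index.name = "sgrna_id"
        return ScreenExperiment(counts, make_sample_sheet(rows), mode="in_vivo")

    def test_two_noisiest_tumours_excluded_and_pairs_averaged(
        self, tumour_expt, qc_manifest
    ):
        out = fs.invivo_replicate_qc(tumour_expt, qc_manifest, n_exclude=2)
        assert set(out.meta["invivo_excluded"]) == {"tumour4", "tumour5"}
        assert list(out.counts.columns) == ["tumour_pair1", "tumour_pair2"]
        metrics = out.meta["invivo_noise_metrics"]
        assert [metrics[f"tumour{j}"] for j in range(6)] == [0, 1, 2, 3, 50, 60]

    def test_too_few_tumours_raises(self, tumour_expt, qc_manifest):
        trimmed = ScreenExperiment(
            tumour_expt.counts.iloc[:, :3], tumour_expt.samples.iloc[:3], mode="in_vivo"
        )
        with pytest.raises(InsufficientReplicatesError):
            fs.invivo_replicate_qc(trimmed, qc_manifest, n_exclude=2)
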
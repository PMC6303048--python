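import itertools
import math

import numpy as np
import pandas as pd
import pytest

import barcodegap as bg


def make_taxonomy(rows):
    df = pd.DataFrame(rows, columns=["specimen_id", "species", "genus", "family"])
    df["site"] = "UDV"
    df["external_cluster_id"] = ""
    return bg.TaxonomyTable(df)


def matrix_from_dict(ids, dist):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in dist.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return bg.DistanceMatrix(ids, d, np.full((n, n), 600.0))


class TestBaseComposition:
    def test_single_uniform_sequence(self):
        aln = bg.Alignment([bg.SequenceRecord("s", "ACGT")])
        comp = bg.base_composition(aln)
        assert comp.as_dict() == {"A": 25.0, "C": 25.0, "G": 25.0, "T": 25.0}

    def test_unweighted_mean_across_sequences(self):
        aln = bg.Alignment(
            [bg.SequenceRecord("a", "AAAA"), bg.SequenceRecord("b", "CCCC")]
        )
        comp = bg.base_composition(aln)
        assert comp.pct_A == 50.0 and comp.pct_C == 50.0
        assert comp.pct_G == 0.0 and comp.pct_T == 0.0

    def test_ambiguous_sites_excluded(self):
        aln = bg.Alignment([bg.SequenceRecord("a", "AANN")])
        assert bg.base_composition(aln).pct_A == 100.0

    def test_sums_to_100(self, sim5):
        aln, _, _ = sim5
        assert sum(bg.base_composition(aln).as_dict().values()) == pytest.approx(100.0, abs=0.05)


class TestRankSummaries:
    def test_two_species_one_genus_pair_counts(self):
        ids = ["a1", "a2", "b1", "b2"]
        tax = make_taxonomy(
            [(i, i[0].upper(), "Gen", "Fam") for i in ids]
        )
        dist = {(x, y): 0.01 if x[0] == y[0] else 0.05
                for x, y in itertools.combinations(ids, 2)}
        dm = matrix_from_dict(ids, dist)
        intra, genus, family = bg.rank_summaries(dm, tax)
        assert (intra.n_comparisons, genus.n_comparisons, family.n_comparisons) == (2, 4, 0)
        assert intra.mean_pct == pytest.approx(1.0)
        assert genus.mean_pct == pytest.approx(5.0)

    def test_single_species_dataset_higher_ranks_empty(self):
        ids = ["a", "b", "c"]
        tax = make_taxonomy([(i, "Sp", "Gen", "Fam") for i in ids])
        dm = matrix_from_dict(ids, {p: 0.01 for p in itertools.combinations(ids, 2)})
        intra, genus, family = bg.rank_summaries(dm, tax)
        assert intra.n_comparisons == 3
        assert genus.n_comparisons == 0 and family.n_comparisons == 0

    def test_combinatorial_pair_counts(self, sim5, sim5_distances):
        _, tax, _ = sim5
        counts = pd.Series(tax.column("species", sim5_distances.ids)).value_counts()
        expected = int(sum(n * (n - 1) // 2 for n in counts))
        intra = bg.rank_summaries(sim5_distances, tax)[0]
        assert intra.n_comparisons == expected

    def test_pair_partition_covers_everything(self, sim5, sim5_distances):
        _, tax, _ = sim5
        masks = bg.summaries._rank_masks(sim5_distances, tax)
        iu = np.triu_indices(len(sim5_distances.ids), k=1)
        stacked = sum(m[iu].astype(int) for m in masks.values())
        assert stacked.max() <= 1  # ranks are mutually exclusive

    def test_matches_brute_force_double_loop(self, sim5, sim5_distances):
        _, tax, _ = sim5
        ids = sim5_distances.ids
        sp = tax.column("species", ids)
        ge = tax.column("genus", ids)
        fa = tax.column("family", ids)
        buckets = {"intraspecific": [], "intrageneric": [], "intrafamilial": []}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = sim5_distances.values[i, j] * 100
                if math.isnan(d):
                    continue
                if sp[i] == sp[j]:
                    buckets["intraspecific"].append(d)
                elif ge[i] == ge[j]:
                    buckets["intrageneric"].append(d)
                elif fa[i] == fa[j]:
                    buckets["intrafamilial"].append(d)
        for summary in bg.rank_summaries(sim5_distances, tax):
            vals = buckets[summary.rank]
            assert summary.n_comparisons == len(vals)
            if vals:
                assert summary.mean_pct == pytest.approx(np.mean(vals))
                assert summary.min_pct == pytest.approx(np.min(vals))
                assert summary.max_pct == pytest.approx(np.max(vals))


class TestSpeciesReports:
    def test_two_species_construction(self):
        ids = ["x1", "x2", "y1"]
        tax = make_taxonomy([("x1", "X", "G", "F"), ("x2", "X", "G", "F"),
                             ("y1", "Y", "G", "F")])
        dm = matrix_from_dict(ids, {("x1", "x2"): 0.005, ("x1", "y1"): 0.04,
                                    ("x2", "y1"): 0.05})
        rx = next(r for r in bg.species_reports(dm, tax) if r.species == "X")
        assert rx.mean_intra_pct == pytest.approx(0.5)
        assert rx.nnd_pct == pytest.approx(4.0)
        assert rx.nearest_species == "Y"
        assert rx.has_barcode_gap

    def test_no_gap_when_max_intra_exceeds_nnd(self):
        # deep within-species split dwarfs the nearest-neighbour distance
        ids = ["x1", "x2", "y1"]
        tax = make_taxonomy([("x1", "X", "G", "F"), ("x2", "X", "G", "F"),
                             ("y1", "Y", "G", "F")])
        dm = matrix_from_dict(ids, {("x1", "x2"): 0.2048, ("x1", "y1"): 0.1807,
                                    ("x2", "y1"): 0.20})
        rx = next(r for r in bg.species_reports(dm, tax) if r.species == "X")
        assert rx.max_intra_pct == pytest.approx(20.48)
        assert rx.nnd_pct == pytest.approx(18.07)
        assert not rx.has_barcode_gap

    def test_singleton_gap_by_convention(self):
        ids = ["x1", "y1", "y2"]
        tax = make_taxonomy([("x1", "X", "G", "F"), ("y1", "Y", "G", "F"),
                             ("y2", "Y", "G", "F")])
        dm = matrix_from_dict(ids, {("x1", "y1"): 0.04, ("x1", "y2"): 0.05,
                                    ("y1", "y2"): 0.002})
        rx = next(r for r in bg.species_reports(dm, tax) if r.species == "X")
        assert rx.n == 1 and rx.mean_intra_pct is None
        assert rx.nnd_pct == pytest.approx(4.0)
        assert rx.has_barcode_gap and "insufficient" in rx.note

    def test_min_nnd_equals_global_min_interspecific(self, sim5, sim5_distances):
        _, tax, _ = sim5
        reports = bg.species_reports(sim5_distances, tax)
        sp = np.array(tax.column("species", sim5_distances.ids))
        inter_mask = sp[:, None] != sp[None, :]
        global_min = np.nanmin(sim5_distances.values[inter_mask]) * 100
        assert min(r.nnd_pct for r in reports) == pytest.approx(global_min)

    def test_nnd_is_lower_bound_on_member_distances(self, sim5, sim5_distances):
        _, tax, _ = sim5
        sp = np.array(tax.column("species", sim5_distances.ids))
        for r in bg.species_reports(sim5_distances, tax):
            inter = sim5_distances.values[np.ix_(sp == r.species, sp != r.species)]
            assert r.nnd_pct <= np.nanmin(inter) * 100 + 1e-9


class TestFlagDivergent:
    def test_threshold_and_sorting(self):
        ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
        tax = make_taxonomy([(i, i[0].upper(), "G", "F") for i in ids])
        dist = {}
        for x, y in itertools.combinations(ids, 2):
            if x[0] == y[0]:
                dist[(x, y)] = {"a": 0.08, "b": 0.03, "c": 0.001}[x[0]]
            else:
                dist[(x, y)] = 0.20
        dm = matrix_from_dict(ids, dist)
        reports = bg.species_reports(dm, tax)
        flagged = bg.flag_divergent(reports, threshold_pct=2.0)
        assert [r.species for r in flagged] == ["A", "B"]
        assert bg.flag_divergent(reports, threshold_pct=0.0) == sorted(
            reports, key=lambda r: -r.max_intra_pct
        )

    def test_no_divergence_empty(self):
        ids = ["a1", "a2"]
        tax = make_taxonomy([(i, "A", "G", "F") for i in ids])
        dm = matrix_from_dict(ids, {("a1", "a2"): 0.0})
        assert bg.flag_divergent(bg.species_reports(dm, tax)) == []
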
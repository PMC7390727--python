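"""Abundance aggregation and its statistical primitives."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pentacensus.census import (
    CensusRow,
    GenomeCount,
    abundance_by_group,
    abundance_by_lbd_family,
    abundance_by_taxon,
    abundance_by_topology,
    abundance_vs_receptor_count,
    genome_summary,
    pentapeptide_histogram,
    pearson_r,
    per_genome_counts,
)
from pentacensus.classify import (
    CYTOSOLIC,
    NO_PENTAPEPTIDE,
    PENTA_ON_SIGNALING,
    TRANSMEMBRANE,
    ReceptorAnnotation,
)
from pentacensus.io_tables import UNCLASSIFIED, ProteomeMeta


def receptor(pid, proteome, penta=False, topology=CYTOSOLIC, families=()):
    return ReceptorAnnotation(
        protein_id=pid,
        proteome_id=proteome,
        has_pentapeptide=penta,
        pentapeptide="NWETF" if penta else None,
        topology=topology,
        lbd_families=frozenset(families),
        architecture=PENTA_ON_SIGNALING if penta else NO_PENTAPEPTIDE,
    )


class TestPerGenomeCounts:
    def test_counts_totals_and_pentapeptides(self):
        ann = [
            receptor("a", "UP1", penta=True),
            receptor("b", "UP1"),
            receptor("c", "UP1"),
        ]
        assert per_genome_counts(ann) == [GenomeCount("UP1", 3, 1)]

    def test_empty_input(self):
        assert per_genome_counts([]) == []

    def test_two_proteomes(self):
        ann = [receptor("a", "UP1"), receptor("b", "UP2", penta=True)]
        counts = {c.proteome_id: c for c in per_genome_counts(ann)}
        assert counts["UP1"] == GenomeCount("UP1", 1, 0)
        assert counts["UP2"] == GenomeCount("UP2", 1, 1)


class TestGenomeSummary:
    def test_constant_counts(self):
        counts = [GenomeCount(f"UP{i}", 10, 0) for i in range(3)]
        assert genome_summary(counts) == (10.0, 0.0)

    def test_sample_standard_deviation(self):
        counts = [GenomeCount("UP1", 1, 0), GenomeCount("UP2", 3, 0)]
        mean, sd = genome_summary(counts)
        assert mean == 2.0
        assert sd == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            genome_summary([])

    def test_single_genome_has_undefined_sd(self):
        mean, sd = genome_summary([GenomeCount("UP1", 7, 1)])
        assert mean == 7.0 and sd is None


class TestHistogram:
    def test_zero_count_genomes_excluded(self):
        counts = [
            GenomeCount("UP1", 4, 1),
            GenomeCount("UP2", 4, 1),
            GenomeCount("UP3", 4, 2),
            GenomeCount("UP4", 4, 0),
        ]
        assert pentapeptide_histogram(counts) == {1: 2, 2: 1}

    def test_all_zero(self):
        assert pentapeptide_histogram([GenomeCount("UP1", 3, 0)]) == {}

    def test_extreme_genome(self):
        assert pentapeptide_histogram([GenomeCount("UP1", 30, 20)]) == {20: 1}


class TestAbundanceByGroup:
    def test_single_key_grouping(self):
        ann = [receptor(f"p{i}", "UP1", penta=(i == 0)) for i in range(4)]
        rows = abundance_by_group(ann, lambda a: "X")
        assert rows == [CensusRow("X", 4, 1, 25.0)]

    def test_multi_membership_counts_in_every_family(self):
        ann = [receptor("p1", "UP1", penta=True, families=("GAF", "PAS_3"))]
        rows = {r.group: r for r in abundance_by_lbd_family(ann)}
        assert rows["GAF"].total_receptors == 1
        assert rows["PAS_3"].total_receptors == 1

    def test_no_key_pools_into_unclassified(self):
        ann = [receptor("p1", "UP1")]
        rows = abundance_by_lbd_family(ann)
        assert rows == [CensusRow(UNCLASSIFIED, 1, 0, 0.0)]

    def test_topology_grouping(self):
        ann = [
            receptor("p1", "UP1", penta=True, topology=TRANSMEMBRANE),
            receptor("p2", "UP1", topology=TRANSMEMBRANE),
            receptor("p3", "UP1", topology=CYTOSOLIC),
            receptor("p4", "UP1", topology=CYTOSOLIC),
        ]
        rows = {r.group: r for r in abundance_by_topology(ann)}
        assert rows[TRANSMEMBRANE] == CensusRow(TRANSMEMBRANE, 2, 1, 50.0)
        assert rows[CYTOSOLIC] == CensusRow(CYTOSOLIC, 2, 0, 0.0)


class TestAbundanceByTaxon:
    @staticmethod
    def meta(**orders):
        out = {}
        for pid, order in orders.items():
            out[pid] = ProteomeMeta(
                pid,
                {
                    "superkingdom": "Bacteria",
                    "phylum": "Proteobacteria",
                    "class": "Gammaproteobacteria",
                    "order": order,
                },
            )
        return out

    def test_half_pentapeptide_order(self):
        ann = [receptor(f"p{i}", "UP1", penta=(i < 2)) for i in range(4)]
        rows = abundance_by_taxon(ann, self.meta(UP1="O1"), "order")
        assert rows == [CensusRow("O1", 4, 2, 50.0)]

    def test_single_phylum_conserves_global_totals(self):
        ann = [receptor(f"p{i}", "UP1", penta=(i == 0)) for i in range(5)]
        rows = abundance_by_taxon(ann, self.meta(UP1="O1"), "phylum")
        assert rows[0].total_receptors == 5
        assert rows[0].pentapeptide_receptors == 1

    def test_unsupported_rank_raises(self):
        with pytest.raises(ValueError, match="genus"):
            abundance_by_taxon([], {}, "genus")

    def test_orphan_proteomes_listed(self):
        ann = [receptor("p1", "UPX")]
        with pytest.raises(KeyError, match="UPX"):
            abundance_by_taxon(ann, self.meta(UP1="O1"), "order")

    def test_phylum_totals_sum_over_orders(self, small_annotations):
        annotations, metadata, _, _ = small_annotations
        by_phylum = {r.group: r for r in abundance_by_taxon(annotations, metadata, "phylum")}
        by_order = abundance_by_taxon(annotations, metadata, "order")
        order_to_phylum = {
            m.rank("order"): m.rank("phylum") for m in metadata.values()
        }
        summed = {}
        for row in by_order:
            summed[order_to_phylum[row.group]] = (
                summed.get(order_to_phylum[row.group], 0) + row.total_receptors
            )
        assert {k: v.total_receptors for k, v in by_phylum.items()} == summed


class TestAbundanceVsCount:
    def test_perfect_anticorrelation(self):
        counts = [
            GenomeCount(f"UP{c}", c, round(c * (100 - c) / 100)) for c in (10, 20, 50)
        ]
        points, r = abundance_vs_receptor_count(counts, cap_percentile=None)
        assert [p.pooled_abundance_percent for p in points] == [90.0, 80.0, 50.0]
        assert r == pytest.approx(-1.0)

    def test_constant_abundance_has_no_correlation(self):
        counts = [GenomeCount(f"UP{c}", c, c // 2) for c in (2, 4, 8)]
        points, r = abundance_vs_receptor_count(counts, cap_percentile=None)
        assert r is None

    def test_min_genomes_filters_sparse_counts(self):
        counts = [
            GenomeCount("UP1", 2, 1),
            GenomeCount("UP2", 2, 0),
            GenomeCount("UP3", 9, 0),
        ]
        points, _ = abundance_vs_receptor_count(
            counts, min_genomes=2, cap_percentile=None
        )
        assert [p.receptor_count for p in points] == [2]

    def test_pooled_not_averaged(self):
        # two genomes at count 2: 2/2 and 0/2 pool to 50%, not mean-of-ratios
        # ambiguity (here equal, so distinguish with unequal totals at count 3)
        counts = [GenomeCount("UP1", 3, 3), GenomeCount("UP2", 3, 0),
                  GenomeCount("UP3", 3, 0)]
        points, _ = abundance_vs_receptor_count(counts, cap_percentile=None)
        assert points[0].pooled_abundance_percent == pytest.approx(100 * 3 / 9)


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100),
            min_size=3,
            max_size=30,
        ).filter(lambda xs: len(set(xs)) > 1)
    )
    def test_agrees_with_direct_formula_and_scipy(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = [x + rng.normal() for x in xs]
        x, y = np.array(xs, dtype=float), np.array(ys)
        n = len(x)
        # direct two-pass formula oracle
        oracle = (n * (x * y).sum() - x.sum() * y.sum()) / math.sqrt(
            (n * (x * x).sum() - x.sum() ** 2) * (n * (y * y).sum() - y.sum() ** 2)
        )
        r = pearson_r(x, y)
        assert r == pytest.approx(oracle, abs=1e-9)
        assert r == pytest.approx(scipy.stats.pearsonr(x, y).statistic, abs=1e-9)


class TestConservation:
    def test_single_membership_groupings_conserve_totals(self, small_annotations):
        annotations, metadata, _, _ = small_annotations
        n = len(annotations)
        n_penta = sum(a.has_pentapeptide for a in annotations)
        for rows in (
            abundance_by_topology(annotations),
            abundance_by_taxon(annotations, metadata, "phylum"),
            abundance_by_taxon(annotations, metadata, "order"),
        ):
            assert sum(r.total_receptors for r in rows) == n
            assert sum(r.pentapeptide_receptors for r in rows) == n_penta
            assert all(0.0 <= r.abundance_percent <= 100.0 for r in rows)
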
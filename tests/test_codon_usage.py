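import numpy as np
import pandas as pd
import pytest

from proteotherm.codon_usage import (
    ALL_CODONS,
    correspondence_analysis,
    count_codons,
    detect_preferred_codons,
    effective_number_of_codons,
    expected_nc,
    nc_table,
    rscu,
    synonymous_families,
    variable_sense_codons,
)
from proteotherm.substitutions import WAGModel
from proteotherm.synthetic import _assign_codons, simulate_pair_set


def _series(counts: dict) -> pd.Series:
    s = pd.Series(0, index=list(ALL_CODONS))
    for c, n in counts.items():
        s[c] = n
    return s


def _nc_oracle(counts: pd.Series) -> float | None:
    """Literal transcription of Wright's estimator, kept independent of the
    implementation under test (explicit loops, no shared helpers)."""
    fams = synonymous_families()
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, cods in fams.items():
        if len(cods) == 1:
            continue
        ns = [int(counts[c]) for c in cods]
        n = sum(ns)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            per_class[len(cods)].append(f)
    if any(not v for v in per_class.values()):
        return None
    fbar = {k: sum(v) / len(v) for k, v in per_class.items()}
    return min(2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6], 62.0)


class TestCountCodons:
    def test_terminal_stop_excluded(self):
        table, warnings = count_codons({"g": "ATGAAATAA"})
        assert table.counts.loc["g", "ATG"] == 1
        assert table.counts.loc["g", "AAA"] == 1
        assert table.counts.loc["g"].sum() == 2
        assert not warnings

    def test_empty_orf_rejected(self):
        with pytest.raises(ValueError):
            count_codons({"g": ""})

    def test_internal_stop_skipped_with_warning(self):
        table, warnings = count_codons({"g": "ATGTAAAAATAA"})
        assert table.counts.loc["g"].sum() == 2
        assert "internal stop" in warnings["g"][0]

    def test_row_sum_bookkeeping(self, rng):
        sense = list(variable_sense_codons())
        for _ in range(5):
            length = int(rng.integers(20, 60))
            seq = "".join(rng.choice(sense, size=length)) + "TAA"
            table, _ = count_codons({"g": seq})
            assert table.counts.loc["g"].sum() == length


class TestRSCU:
    def test_uniform_family_gives_one(self):
        vals = rscu(_series({"GTT": 5, "GTC": 5, "GTA": 5, "GTG": 5}))
        assert all(vals[c] == pytest.approx(1.0) for c in ("GTT", "GTC", "GTA", "GTG"))

    def test_single_codon_family(self):
        vals = rscu(_series({"GTG": 8}))
        assert vals["GTG"] == pytest.approx(4.0)
        assert vals["GTT"] == pytest.approx(0.0)

    def test_unused_family_is_undefined(self):
        vals = rscu(_series({"GTG": 8}))
        assert np.isnan(vals["CCC"])

    def test_family_sums_equal_family_size(self, rng):
        counts = _series({c: int(rng.integers(0, 30)) for c in ALL_CODONS})
        vals = rscu(counts)
        for aa, cods in synonymous_families().items():
            fam = [vals[c] for c in cods]
            if not np.isnan(fam).any():
                assert sum(fam) == pytest.approx(len(cods))


class TestNc:
    def test_single_codon_per_amino_acid_is_20(self):
        counts = _series({cods[0]: 50 for cods in synonymous_families().values()})
        assert effective_number_of_codons(counts).nc == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self):
        counts = _series({c: 10000 for aa, cods in synonymous_families().items()
                          for c in cods})
        assert effective_number_of_codons(counts).nc == pytest.approx(61.0, abs=0.05)

    def test_missing_degeneracy_class_undefined(self):
        counts = _series({"GCT": 10, "GCC": 12, "TTT": 4, "TTC": 5, "CTG": 7,
                          "CTA": 6})  # no Ile codons: 3-fold class absent
        assert effective_number_of_codons(counts).nc is None

    def test_matches_independent_oracle_on_random_genes(self, rng):
        sense = [c for cods in synonymous_families().values() for c in cods]
        for _ in range(50):
            n_codons = int(rng.integers(30, 400))
            usage = rng.dirichlet(np.ones(len(sense)) * rng.uniform(0.05, 2.0))
            draw = rng.choice(sense, size=n_codons, p=usage)
            counts = _series(pd.Series(draw).value_counts().to_dict())
            mine = effective_number_of_codons(counts).nc
            oracle = _nc_oracle(counts)
            if oracle is None:
                assert mine is None
            else:
                assert mine == pytest.approx(oracle, rel=1e-12)


class TestExpectedNc:
    def test_balanced_gc3(self):
        assert expected_nc(0.5) == pytest.approx(60.5)

    def test_strong_at_bias(self):
        assert expected_nc(0.1) == pytest.approx(2.1 + 29 / 0.82, rel=1e-6)

    def test_bell_shape_with_linear_asymmetry(self):
        # the curve is bell-shaped around s ~ 0.5; the linear term makes
        # expected_nc(1-s) - expected_nc(s) exactly 1 - 2s
        for s in (0.1, 0.25, 0.42):
            assert expected_nc(1 - s) - expected_nc(s) == pytest.approx(1 - 2 * s)
            assert expected_nc(0.5) > expected_nc(s)
            assert expected_nc(0.5) > expected_nc(1 - s)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.5])
    def test_boundary_rejected(self, s):
        with pytest.raises(ValueError):
            expected_nc(s)


def _gradient_table(seed=11, n_genes=80, total=24000):
    pairs, _ = simulate_pair_set(n_genes=n_genes, total_codons=total, seed=seed)
    orfs = {f"g{i:03d}": aln.records[1].seq for i, aln in enumerate(pairs)}
    table, _ = count_codons(orfs)
    return table


class TestCorrespondenceAnalysis:
    def test_proportional_rows_have_zero_inertia(self):
        base = {c: 3 for c in variable_sense_codons()}
        counts = pd.DataFrame(
            [_series(base), _series({c: 6 for c in base})],
            index=["g1", "g2"])[list(ALL_CODONS)]
        from proteotherm.codon_usage import CodonCountTable

        table = CodonCountTable(counts=counts,
                                gc3=pd.Series({"g1": 0.5, "g2": 0.5}))
        ca = correspondence_analysis(table)
        assert ca.inertia_share.sum() == pytest.approx(0.0, abs=1e-12)

    def test_toy_table_matches_eigen_oracle(self):
        # independent CA route: eigen-decomposition of the row-profile operator
        N = np.array([[10.0, 2.0, 5.0], [3.0, 9.0, 4.0], [6.0, 1.0, 12.0]])
        P = N / N.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        evals, evecs = np.linalg.eigh(S @ S.T)
        lead = np.sqrt(evals[-1])
        row_coord_oracle = evecs[:, -1] * lead / np.sqrt(r)

        from proteotherm.codon_usage import CodonCountTable

        codons = list(ALL_CODONS[:3])
        counts = pd.DataFrame(0, index=["a", "b", "c"], columns=list(ALL_CODONS))
        counts.loc[:, codons] = N.astype(int)
        table = CodonCountTable(counts=counts,
                                gc3=pd.Series({"a": 0.3, "b": 0.5, "c": 0.7}))
        ca = correspondence_analysis(table, codon_set=codons)
        mine = ca.gene_coords["axis1"].to_numpy()
        assert np.allclose(np.abs(mine), np.abs(row_coord_oracle), atol=1e-10)

    def test_row_duplication_leaves_coordinates_unchanged(self):
        table = _gradient_table()
        ca = correspondence_analysis(table)
        doubled = table.counts.copy()
        doubled.loc["g000"] *= 2
        from proteotherm.codon_usage import CodonCountTable

        ca2 = correspondence_analysis(
            CodonCountTable(counts=doubled, gc3=table.gc3))
        # profiles, not totals, drive CA: doubling a gene's counts leaves its
        # profile unchanged; only the slight column-mass shift moves the axes
        span = ca.gene_coords["axis1"].max() - ca.gene_coords["axis1"].min()
        shift = abs(ca.gene_coords.at["g000", "axis1"]
                    - ca2.gene_coords.at["g000", "axis1"])
        assert shift < 0.02 * span

    def test_axis1_tracks_gc3_on_gradient_simulation(self):
        ca = correspondence_analysis(_gradient_table())
        assert ca.axis1_gc3_corr > 0.9


class TestPreferredCodons:
    def _constructed(self, rng):
        model = WAGModel.bundled()
        orfs = {}
        for g in range(60):
            aa = rng.choice(20, size=300, p=model.pi)
            if g < 6:
                orfs[f"hi{g:02d}"] = "".join(_assign_codons(aa, 1.0, rng))
            elif g >= 54:
                orfs[f"lo{g:02d}"] = "".join(_assign_codons(aa, 0.0, rng))
            else:
                orfs[f"mid{g:02d}"] = "".join(_assign_codons(aa, 0.5, rng))
        table, _ = count_codons(orfs)
        return table

    def test_gc_only_extremes_yield_exact_gc_ended_set(self, rng):
        table = self._constructed(rng)
        ca = correspondence_analysis(table)
        fop = detect_preferred_codons(ca, table)
        gc_ended_variable = {c for c in variable_sense_codons() if c[2] in "GC"}
        assert set(fop.codons) == gc_ended_variable
        assert all(fop.gc_ended.values())

    def test_identical_usage_between_extremes_gives_empty_set(self, rng):
        # every gene carries literally the same codon counts, so the pooled
        # high- and low-extreme usages cannot differ
        model = WAGModel.bundled()
        aa = rng.choice(20, size=250, p=model.pi)
        seq = "".join(_assign_codons(aa, 0.5, rng))
        orfs = {f"g{g:02d}": seq for g in range(40)}
        table, _ = count_codons(orfs)
        ca = correspondence_analysis(table)
        fop = detect_preferred_codons(ca, table)
        assert fop.codons == ()

    def test_detection_invariant_to_gene_input_order(self, rng):
        table = self._constructed(rng)
        ca = correspondence_analysis(table)
        fop = detect_preferred_codons(ca, table)
        from proteotherm.codon_usage import CodonCountTable

        rev = CodonCountTable(counts=table.counts.iloc[::-1],
                              gc3=table.gc3.iloc[::-1])
        ca_rev = correspondence_analysis(rev)
        fop_rev = detect_preferred_codons(ca_rev, rev)
        assert set(fop.codons) == set(fop_rev.codons)


class TestPartitionSimilarity:
    def test_nc_close_between_species_with_identical_usage(self):
        pairs, _ = simulate_pair_set(n_genes=100, total_codons=30000, seed=11)
        donor = {f"g{i}": a.records[0].seq for i, a in enumerate(pairs)}
        focal = {f"g{i}": a.records[1].seq for i, a in enumerate(pairs)}
        nc_d = nc_table(count_codons(donor)[0])["nc"].mean()
        nc_f = nc_table(count_codons(focal)[0])["nc"].mean()
        assert abs(nc_d - nc_f) < 1.0
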
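"""A-site assignment, gene filtering, differential occupancy and density."""

import math

import numpy as np
import pandas as pd
import pytest

from frameshift_scan.codons import CodingSequence
from frameshift_scan.ribo_occupancy import (
    CodonOccupancyProfile,
    NoGenesPassFilterError,
    RpfAlignment,
    asite_codon,
    count_asite_codons,
    density_comparison,
    differential_occupancy,
)
from frameshift_scan.synthetic_data import SimulationConfig, generate_cds_set, simulate_rpf


@pytest.fixture(scope="module")
def long_cds():
    # 40 sense codons incl. the start; terminal TAA
    return CodingSequence.from_raw("t1", "ATG" + "GCT" * 39 + "TAA")


class TestAsiteAssignment:
    def test_offset_fifteen_lands_on_codon_five(self, long_cds):
        assert asite_codon(RpfAlignment("t1", 0, 30), long_cds) == long_cds.codon(5)

    def test_shift_by_codon(self, long_cds):
        assert asite_codon(RpfAlignment("t1", 3, 30), long_cds) == long_cds.codon(6)

    def test_off_frame_position_floors_to_codon(self, long_cds):
        # 5' end at nt 1 -> A-site nt 16 -> floor(16/3) = codon 5
        assert asite_codon(RpfAlignment("t1", 1, 30), long_cds) == long_cds.codon(5)

    def test_rejections_return_none(self, long_cds):
        assert asite_codon(RpfAlignment("t1", -20, 30), long_cds) is None  # before CDS
        far = 3 * long_cds.n_codons  # beyond the stop
        assert asite_codon(RpfAlignment("t1", far, 30), long_cds) is None
        assert asite_codon(RpfAlignment("t1", 0, 15), long_cds) is None  # A-site outside read
        # stop codon excluded by default, included on request
        stop_pos = 3 * (long_cds.n_codons - 1) - 15
        assert asite_codon(RpfAlignment("t1", stop_pos, 30), long_cds) is None
        assert asite_codon(RpfAlignment("t1", stop_pos, 30), long_cds, include_stop=True) == "TAA"


def _rpf_rows(tid, codon_indices, condition, length=30):
    return pd.DataFrame(
        {
            "transcript_id": tid,
            "five_prime_pos": [3 * i - 15 for i in codon_indices],
            "read_length": length,
            "condition": condition,
            "replicate": 1,
        }
    )


class TestGeneFilter:
    def test_gene_below_floor_in_one_condition_excluded_everywhere(self, long_cds):
        other = CodingSequence.from_raw("t2", "ATG" + "CGT" * 39 + "TAA")
        cds_map = {"t1": long_cds, "t2": other}
        aln = pd.concat(
            [
                _rpf_rows("t1", [10] * 99, "control"),  # below floor in control
                _rpf_rows("t1", [10] * 500, "treated"),
                _rpf_rows("t2", [10] * 120, "control"),
                _rpf_rows("t2", [10] * 120, "treated"),
            ]
        )
        profiles = count_asite_codons(aln, cds_map, min_gene_reads=100)
        for p in profiles.values():
            assert p.genes_retained == frozenset({"t2"})
        assert profiles["control"].counts["CGT"] == 120

    def test_all_genes_retained_when_above_floor(self, long_cds):
        cds_map = {"t1": long_cds}
        aln = pd.concat(
            [_rpf_rows("t1", [10] * 100, "control"), _rpf_rows("t1", [10] * 100, "treated")]
        )
        profiles = count_asite_codons(aln, cds_map, min_gene_reads=100)
        assert profiles["control"].genes_retained == frozenset({"t1"})
        assert profiles["control"].counts["GCT"] == 100

    def test_empty_retained_set_raises(self, long_cds):
        aln = pd.concat(
            [_rpf_rows("t1", [10] * 5, "control"), _rpf_rows("t1", [10] * 5, "treated")]
        )
        with pytest.raises(NoGenesPassFilterError):
            count_asite_codons(aln, {"t1": long_cds}, min_gene_reads=100)


class TestDifferentialOccupancy:
    def _profile(self, condition, counts):
        return CodonOccupancyProfile(
            condition=condition, counts=counts, genes_retained=frozenset({"g"})
        )

    def test_identical_profiles_give_zero_shift(self):
        p = self._profile("a", {"TTA": 10, "TTG": 90})
        table = differential_occupancy(p, p)
        assert (table["log2_shift"] == 0).all()

    def test_hand_arithmetic_without_pseudocount(self):
        ctrl = self._profile("control", {"TTA": 10, "TTG": 90})
        treat = self._profile("treated", {"TTA": 50, "TTG": 50})
        table = differential_occupancy(treat, ctrl, pseudocount=0).set_index("codon")
        assert table.loc["TTA", "log2_shift"] == pytest.approx(math.log2(0.5 / 0.1))
        assert table.loc["TTA", "log2_shift"] == pytest.approx(2.322, abs=1e-3)

    def test_frequencies_sum_to_one(self):
        ctrl = self._profile("control", {"TTA": 7, "CTG": 13, "GGG": 5})
        treat = self._profile("treated", {"TTA": 11, "CTG": 3, "GGG": 9})
        table = differential_occupancy(treat, ctrl)
        assert table["freq_ctrl"].sum() == pytest.approx(1, abs=1e-12)
        assert table["freq_treat"].sum() == pytest.approx(1, abs=1e-12)

    def test_mismatched_gene_sets_rejected(self):
        a = self._profile("a", {"TTA": 1})
        b = CodonOccupancyProfile("b", {"TTA": 1}, frozenset({"other"}))
        with pytest.raises(ValueError):
            differential_occupancy(a, b)

    def test_planted_stall_ranks_target_codon_first(self, small_config, small_cds_set):
        rpf = simulate_rpf(small_cds_set, small_config, small_config.streams()["rpf"])
        cds_map = {c.id: c for c in small_cds_set}
        profiles = count_asite_codons(rpf, cds_map, min_gene_reads=100)
        table = differential_occupancy(profiles["treated"], profiles["control"])
        assert table.loc[table["log2_shift"].idxmax(), "codon"] == "TTA"

    def test_shift_monotone_in_stall_factor(self):
        shifts = []
        for factor in (2, 5, 10):
            cfg = SimulationConfig(seed=19, n_genes=40, reads_per_gene=400, stall_factor=factor)
            streams = cfg.streams()
            cds = generate_cds_set(cfg, streams["cds"])
            rpf = simulate_rpf(cds, cfg, streams["rpf"])
            profiles = count_asite_codons(rpf, {c.id: c for c in cds}, min_gene_reads=100)
            table = differential_occupancy(profiles["treated"], profiles["control"])
            table = table.set_index("codon")
            assert table["log2_shift"].idxmax() == "TTA"
            shifts.append(table.loc["TTA", "log2_shift"])
        assert shifts[0] < shifts[1] < shifts[2]

    def test_permutation_null_below_planted_shift(self, small_config, small_cds_set):
        """Relabeling reads between conditions destroys the planted TTA
        shift in >= 95% of seeded permutations."""
        rpf = simulate_rpf(small_cds_set, small_config, small_config.streams()["rpf"])
        cds_map = {c.id: c for c in small_cds_set}
        profiles = count_asite_codons(rpf, cds_map, min_gene_reads=100)
        observed = (
            differential_occupancy(profiles["treated"], profiles["control"])
            .set_index("codon")
            .loc["TTA", "log2_shift"]
        )
        rng = np.random.default_rng(123)
        n_perm, n_below = 50, 0
        labels = rpf["condition"].to_numpy()
        for _ in range(n_perm):
            perm = rpf.assign(condition=rng.permutation(labels))
            p = count_asite_codons(perm, cds_map, min_gene_reads=100)
            t = differential_occupancy(p["treated"], p["control"])
            n_below += t["log2_shift"].abs().max() < observed
        assert n_below >= 0.95 * n_perm


class TestDensityComparison:
    def test_uniform_coverage_gives_unit_density(self, long_cds):
        idx = list(range(5, 35))
        aln = pd.concat([_rpf_rows("t1", idx, "control"), _rpf_rows("t1", idx, "treated")])
        table = density_comparison(aln, {"t1": long_cds}, min_gene_reads=25)
        # one read at each of 30 occurrences over 40 sense codons: covered
        # codons have density 40/30, and both conditions match exactly
        assert (table["mean_density_ctrl"] == table["mean_density_treat"]).all()
        assert table["log2_ratio"].dropna().abs().max() == pytest.approx(0.0)

    def test_scale_invariance_under_depth_change(self, long_cds):
        idx = list(range(5, 35))
        aln = pd.concat(
            [_rpf_rows("t1", idx, "control"), _rpf_rows("t1", idx * 3, "treated")]
        )
        table = density_comparison(aln, {"t1": long_cds}, min_gene_reads=25)
        assert table["log2_ratio"].dropna().abs().max() == pytest.approx(0.0)

    def test_planted_stall_has_highest_density_ratio(self, small_config, small_cds_set):
        rpf = simulate_rpf(small_cds_set, small_config, small_config.streams()["rpf"])
        table = density_comparison(
            rpf, {c.id: c for c in small_cds_set}, min_gene_reads=25
        ).set_index("codon")
        ratios = table["log2_ratio"].dropna()
        assert ratios.idxmax() == "TTA"
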
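import numpy as np
import pandas as pd
import pytest

from finesgs import (
    FilterThresholds,
    GenotypeMatrix,
    classify_age,
    diversity,
    hard_filter,
    ho_he_ttest,
    maf_filter,
)
from finesgs.datatypes import InputError
from finesgs.io import DegenerateVarianceError, read_vcf, SampleMismatchError


def _gm_with_info(info: pd.DataFrame) -> GenotypeMatrix:
    n_loci = len(info)
    calls = np.tile(np.array([0, 1, 2, 1], dtype=np.int8)[:, None], (1, n_loci))
    return GenotypeMatrix([f"s{i}" for i in range(4)], [f"l{j}" for j in range(n_loci)], calls, info)


PASSING = dict(FS=10.0, HaplotypeScore=5.0, MQ=60.0, QD=20.0, ReadPosRankSum=0.0, MQRankSum=0.0)


class TestHardFilter:
    def test_fs_above_60_removed(self):
        info = pd.DataFrame([PASSING, {**PASSING, "FS": 70.0}])
        out = hard_filter(_gm_with_info(info), FilterThresholds())
        assert out.loci == ["l0"]

    def test_mqranksum_boundary_is_strict(self):
        info = pd.DataFrame([{**PASSING, "MQRankSum": -12.5}, PASSING])
        out = hard_filter(_gm_with_info(info), FilterThresholds())
        assert out.loci == ["l1"]

    def test_each_criterion_fails_one_site(self):
        # six sites, each violating exactly one criterion -> none retained
        failures = [
            {**PASSING, "FS": 60.01},
            {**PASSING, "HaplotypeScore": 13.01},
            {**PASSING, "MQ": 39.99},
            {**PASSING, "QD": 1.99},
            {**PASSING, "ReadPosRankSum": -8.01},
            {**PASSING, "MQRankSum": -12.5},
        ]
        out = hard_filter(_gm_with_info(pd.DataFrame(failures)), FilterThresholds())
        assert out.n_loci == 0

    def test_boundary_values_that_pass(self):
        edge = dict(FS=60.0, HaplotypeScore=13.0, MQ=40.0, QD=2.0,
                    ReadPosRankSum=-8.0, MQRankSum=-12.49)
        out = hard_filter(_gm_with_info(pd.DataFrame([edge])), FilterThresholds())
        assert out.n_loci == 1

    def test_idempotent(self):
        info = pd.DataFrame([PASSING, {**PASSING, "FS": 70.0}, PASSING])
        once = hard_filter(_gm_with_info(info), FilterThresholds())
        twice = hard_filter(once, FilterThresholds())
        assert once.loci == twice.loci
        assert np.array_equal(once.calls, twice.calls)

    def test_missing_annotations_skipped_with_all_loci_kept(self, caplog):
        gm = _gm_with_info(pd.DataFrame({"FS": [10.0, 20.0]}))
        out = hard_filter(gm, FilterThresholds())
        assert out.n_loci == 2


class TestMafFilter:
    def test_boundary_is_strict(self):
        # locus 0: p = 0.05 exactly -> dropped; locus 1: p = 0.5 -> kept
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[0, 0] = 1          # 1 alt of 20 alleles = 0.05
        calls[:5, 1] = 2         # p = 0.5
        gm = GenotypeMatrix([f"s{i}" for i in range(10)], ["a", "b"], calls)
        out = maf_filter(gm, 0.05)
        assert out.loci == ["b"]

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, rng.uniform(0.01, 0.5, 300), size=(40, 300)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = -1
        gm = GenotypeMatrix([f"s{i}" for i in range(40)], [f"l{j}" for j in range(300)], calls)
        out = maf_filter(gm, 0.05)
        kept = set(out.loci)
        for j, locus in enumerate(gm.loci):
            col = calls[:, j]
            obs = col[col >= 0]
            if obs.size == 0:
                assert locus not in kept
                continue
            p = obs.sum() / (2 * obs.size)
            assert (locus in kept) == (min(p, 1 - p) > 0.05)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, rng.uniform(0.02, 0.5, 50), size=(20, 50)).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(20)], [f"l{j}" for j in range(50)], calls)
        once = maf_filter(gm)
        assert maf_filter(once).loci == once.loci


class TestClassifyAge:
    @pytest.mark.parametrize(
        "dbh, expected",
        [(5.0, "sapling"), (7.49, "sapling"), (7.5, "adult"), (22.49, "adult"),
         (22.5, "mature"), (40.0, "mature")],
    )
    def test_boundaries(self, dbh, expected):
        assert classify_age(dbh) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(InputError):
            classify_age(0.0)


class TestDiversity:
    def _meta(self, ids):
        return pd.DataFrame(
            {"id": ids, "population": "P", "patch": "A", "dbh": 10.0, "age_class": "adult"}
        )

    def test_hand_worked_single_locus(self):
        # genotypes {0,1,1,2}: HO=0.5, p=0.5, HE=(8/7)*0.5, Fis=1-0.875
        gm = GenotypeMatrix(["a", "b", "c", "d"], ["l0"],
                            np.array([[0], [1], [1], [2]], dtype=np.int8))
        row = diversity(gm, self._meta(["a", "b", "c", "d"]), group="patch").iloc[0]
        assert row["ho"] == pytest.approx(0.5)
        assert row["he"] == pytest.approx(8 / 7 * 0.5)
        assert row["fis"] == pytest.approx(1 - 0.5 / (8 / 7 * 0.5))
        assert row["num_indv"] == pytest.approx(4.0)

    def test_monomorphic_reports_zero(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["l0"], np.zeros((3, 1), dtype=np.int8))
        row = diversity(gm, self._meta(["a", "b", "c"]), group="patch").iloc[0]
        assert row["ho"] == 0.0 and row["he"] == 0.0
        assert np.isnan(row["fis"])

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, 60), size=(12, 60)).astype(np.int8)
        ids = [f"s{i}" for i in range(12)]
        gm = GenotypeMatrix(ids, [f"l{j}" for j in range(60)], calls)
        base = diversity(gm, self._meta(ids), group="patch").iloc[0]
        perm = rng.permutation(12)
        gm2 = gm.take_samples(perm)
        shuffled = diversity(gm2, self._meta([ids[i] for i in perm]), group="patch").iloc[0]
        for col in ("ho", "he", "fis", "num_indv"):
            assert base[col] == pytest.approx(shuffled[col], abs=1e-12)

    def test_hardy_weinberg_fis_near_zero(self):
        # no selfing, random mating -> mean Fis within 3 SE of zero
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(20):
            p = rng.uniform(0.1, 0.5, 150)
            calls = rng.binomial(2, p, size=(60, 150)).astype(np.int8)
            ids = [f"s{i}" for i in range(60)]
            gm = GenotypeMatrix(ids, [f"l{j}" for j in range(150)], calls)
            vals.append(diversity(gm, self._meta(ids), group="patch").iloc[0]["fis"])
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(vals.size)


class TestHoHeTTest:
    def test_degenerate_when_identical(self):
        with pytest.raises(DegenerateVarianceError):
            ho_he_ttest([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])

    def test_pooled_variance_formula(self):
        res = ho_he_ttest([0.020, 0.019, 0.018], [0.083, 0.083, 0.084])
        assert res.df == 4
        assert res.mean_difference == pytest.approx(-0.0643333, abs=1e-6)
        assert res.t_value == pytest.approx(-96.5, abs=0.05)
        assert res.significance == "***"


class TestReadVcf:
    def test_missing_sample_raises_keyed_error(self, three_patch_dataset, tmp_path):
        from finesgs import write_dataset

        paths = write_dataset(three_patch_dataset, tmp_path)
        meta = pd.read_csv(paths["metadata"], sep="\t").iloc[1:]
        bad = tmp_path / "bad_meta.tsv"
        meta.to_csv(bad, sep="\t", index=False)
        with pytest.raises(SampleMismatchError) as err:
            read_vcf(paths["vcf"], bad)
        assert three_patch_dataset.metadata["id"].iloc[0] in err.value.missing_ids

    def test_triallelic_sites_dropped(self, tmp_path):
        vcf = tmp_path / "tri.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1,length=1000>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb",
        ]
        for pos in range(1, 11):
            alt = "G,C" if pos == 5 else "G"
            lines.append(f"1\t{pos}\tsnp{pos}\tA\t{alt}\t100\t.\t.\tGT\t0/1\t1/1")
        vcf.write_text("\n".join(lines) + "\n")
        meta = tmp_path / "meta.tsv"
        meta.write_text("id\tpopulation\tpatch\tx\ty\tdbh\na\tP\tA\t0\t0\t10\nb\tP\tA\t1\t1\t10\n")
        gm, _, _ = read_vcf(vcf, meta)
        assert gm.n_loci == 9
        assert "snp5" not in gm.loci
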
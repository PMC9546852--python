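"""Catalog construction: clonal filtering, counting, I/O round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chemosig as cs
from chemosig.catalog import MutationRecord, normalise_chrom


def records_frame(rows):
    base = {
        "sample_id": "s1",
        "chrom": "1",
        "pos": 1000,
        "ref": "C",
        "alt": "T",
        "mut_class": "SBS",
        "vaf": 0.5,
        "context": "ACA",
    }
    if not rows:
        return pd.DataFrame(columns=list(base))
    return pd.DataFrame([{**base, **r} for r in rows])


def tiny_meta(sample_ids=("s1",)):
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "donor_id": [f"d{i}" for i in range(len(sample_ids))],
            "tissue": "colon",
            "age": 50.0,
            "capox_cycles": 0,
            "received_platinum": False,
            "received_5fu": False,
            "received_radiotherapy": False,
            "months_since_treatment": np.nan,
        }
    )


class TestFilterClonal:
    def test_strictly_above_threshold_is_kept(self):
        df = records_frame([{"vaf": 0.50}, {"vaf": 0.25}, {"vaf": 0.31}, {"vaf": 0.30}])
        out = cs.filter_clonal(df)
        assert out["vaf"].tolist() == [0.50, 0.31]

    def test_sex_chromosomes_dropped_when_autosomes_only(self):
        df = records_frame([{"chrom": "chrX", "vaf": 0.9}, {"chrom": "7", "vaf": 0.9}])
        assert cs.filter_clonal(df)["chrom"].tolist() == ["7"]
        assert len(cs.filter_clonal(df, autosomes_only=False)) == 2

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(0)
        df = records_frame([{"vaf": float(v), "pos": i} for i, v in enumerate(rng.uniform(0, 1, 200))])
        once = cs.filter_clonal(df)
        assert once.equals(cs.filter_clonal(once))
        assert list(once["pos"]) == sorted(once["pos"])

    def test_beta_mixture_matches_direct_enumeration(self):
        rng = np.random.default_rng(42)
        vafs = np.concatenate([rng.beta(60, 60, 100), rng.beta(4, 20, 50)])
        df = records_frame([{"vaf": float(v)} for v in vafs])
        expected = int(np.sum(vafs > 0.30))
        assert len(cs.filter_clonal(df)) == expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            cs.filter_clonal(records_frame([{}]), vaf_min=1.5)


class TestBuildContextMatrix:
    def test_row_sum_equals_filtered_burden(self):
        df = records_frame([{"pos": p} for p in (1, 2, 3)])
        cm = cs.build_context_matrix(df, tiny_meta(), "SBS96")
        assert cm.counts.loc["s1"].sum() == 3
        assert cm.counts.loc["s1", "A[C>T]A"] == 3

    def test_empty_records_give_zero_matrix_with_correct_shape(self):
        cm = cs.build_context_matrix(records_frame([]).iloc[0:0], tiny_meta(("a", "b")), "DBS78")
        assert cm.counts.shape == (2, 78)
        assert (cm.counts.values == 0).all()

    def test_unknown_sample_raises(self):
        df = records_frame([{"sample_id": "ghost"}])
        with pytest.raises(ValueError, match="ghost"):
            cs.build_context_matrix(df, tiny_meta(), "SBS96")

    def test_filter_then_count_commutes_with_count_then_subtract(self):
        rng = np.random.default_rng(3)
        rows = [
            {"vaf": float(rng.uniform()), "pos": i, "context": "GCT"} for i in range(300)
        ]
        df = records_frame(rows)
        direct = cs.build_context_matrix(cs.filter_clonal(df), tiny_meta(), "SBS96")
        full = cs.build_context_matrix(df.assign(), tiny_meta(), "SBS96")
        dropped = cs.build_context_matrix(
            df[~df.index.isin(cs.filter_clonal(df).index)], tiny_meta(), "SBS96"
        )
        assert ((full.counts - dropped.counts) == direct.counts).all().all()

    def test_multinomial_sampling_recovers_channel_proportions(self, sbs_ref):
        profile = sbs_ref["SBS5"]
        rng = np.random.default_rng(12)
        n = 5000
        counts = rng.multinomial(n, profile.to_numpy())
        chans = np.repeat(profile.index.to_numpy(), counts)
        rows = []
        for chan in chans:
            f5, sub, f3 = chan[0], chan[2:5], chan[6]
            rows.append({"ref": sub[0], "alt": sub[2], "context": f5 + sub[0] + f3, "vaf": 0.5})
        cm = cs.build_context_matrix(records_frame(rows), tiny_meta(), "SBS96")
        res = stats.chisquare(cm.counts.loc["s1"], profile.to_numpy() * n)
        assert res.pvalue > 0.01

    def test_burden_conservation_across_types(self, default_cohort):
        filt = cs.filter_clonal(default_cohort.records)
        bt = cs.burden_table(filt, default_cohort.meta).set_index(["sample_id", "mut_type"])
        for mt, mclass in (("SBS96", "SBS"), ("DBS78", "DBS"), ("ID83", "INDEL")):
            cm = cs.build_context_matrix(filt, default_cohort.meta, mt)
            for sid, total in cm.burdens().items():
                assert total == bt.loc[(sid, mclass), "burden"]


class TestMutationRecord:
    def test_field_invariants_enforced(self):
        with pytest.raises(ValueError):
            MutationRecord("s", "1", 1, "C", "C", "SBS", 0.5)
        with pytest.raises(ValueError):
            MutationRecord("s", "1", 1, "CT", "AA", "SBS", 0.5)
        with pytest.raises(ValueError):
            MutationRecord("s", "1", 1, "C", "T", "SBS", 1.5)
        with pytest.raises(ValueError):
            MutationRecord("s", "1", 1, "C", "T", "SV", 0.5)
        rec = MutationRecord("s", "1", 1, "CT", "AA", "DBS", 0.48)
        assert rec.mut_class == "DBS"

    def test_chrom_normalisation(self):
        assert normalise_chrom("chr7") == "7"
        assert normalise_chrom("7") == "7"


class TestVcfIO:
    def test_round_trip_preserves_channel_counts(self, tmp_path):
        cfg = cs.CohortConfig(
            n_donors_untreated=2, n_donors_treated=1, clones_per_donor=1,
            clones_per_donor_treated=1, aging_intercept=50.0, aging_rate_mean=2.0,
            residual_sd=10.0, n_invitro_subclonal=5, seed=4,
        )
        coh = cs.simulate_cohort(cfg)
        cs.write_cohort(coh, tmp_path, format="vcf")
        back = cs.read_cohort(tmp_path, format="vcf")
        for mt in ("SBS96", "DBS78", "ID83"):
            a = cs.build_context_matrix(cs.filter_clonal(coh.records), coh.meta, mt)
            b = cs.build_context_matrix(cs.filter_clonal(back.records), back.meta, mt)
            assert (a.counts == b.counts).all().all()

    def test_vcf_without_vaf_tag_is_hard_error(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t500\t.\tC\tT\t.\t.\t.\n"
        )
        with pytest.raises(ValueError, match="VAF"):
            cs.read_mutations(vcf, format="vcf")

    def test_empty_vcf_gives_empty_frame(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        df = cs.read_mutations(vcf, format="vcf")
        assert len(df) == 0

    def test_fasta_supplies_sbs_flanks(self, tmp_path):
        fasta = tmp_path / "ref.fa"
        seq = "ACGTACGTAC" * 10
        fasta.write_text(">1\n" + seq + "\n")
        import pyfaidx

        fa = pyfaidx.Fasta(str(fasta))
        # pos 6 (1-based) is C with flanks A (pos5) and G (pos7)
        df = records_frame([{"pos": 6, "ref": "C", "alt": "A"}]).drop(columns=["context"])
        cm = cs.build_context_matrix(df, tiny_meta(), "SBS96", fasta=fa)
        assert cm.counts.loc["s1", "A[C>A]G"] == 1
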
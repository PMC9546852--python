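"""Synthetic cohort generator with the generative structure the analysis assumes.

Emulated features, with defaults set to the study conditions the pipeline
targets:

* linear age-related substitution accumulation (43 mutations/year) with a
  per-donor random intercept and clone-level residual noise;
* per-chemotherapy-cycle platinum substitutions (105/cycle) with coupled
  doublet substitutions at a fixed DBS:SBS thinning ratio (1:26);
* all-or-none 5-FU activation drawn per clone (both inter- and intra-donor
  heterogeneity), Normal(265, 195) mutations when active;
* radiotherapy ID8-type indels (Normal(80, 15)) with correlated simple
  structural deletions (~0.18 per ID8 mutation, 50 bp - 10 kb, no
  breakpoint microhomology) and occasional complex SV clusters;
* clonal VAFs centred at 0.5 and in-vitro subclonal spike-ins with VAF
  mass below 0.3, to be removed by the clonal filter.

Counts are truncated-rounded Normals (matching reported SDs, overdispersed
relative to Poisson) for the headline processes and Poisson for small
background processes.  Channels are drawn multinomially from the process's
signature profile, and every realised per-process count is recorded
exactly in the ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .channels import channels_for
from .reference import synthetic_reference_set

_SBS_SUB = {"C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
            "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G")}


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic treated/untreated cohort.

    Every rate and effect size is config-overridable; the defaults encode
    the study conditions (aging rate 43/yr, platinum 105 SBS/cycle with a
    1:26 DBS:SBS ratio, bimodal 5-FU at 265 +- 195, radiation ID8 80 +- 15
    with coupled deletions).
    """

    n_donors_untreated: int = 12
    n_donors_treated: int = 6
    age_range: tuple[float, float] = (20.0, 80.0)
    clones_per_donor: int = 3
    clones_per_donor_treated: int = 4
    tissue: str = "colon"

    aging_rate_mean: float = 43.0
    aging_intercept: float = 100.0
    donor_sd: float = 100.0
    residual_sd: float = 150.0
    aging_mix: dict = field(default_factory=lambda: {"SBS1": 0.3, "SBS5": 0.5, "SBS18": 0.2})
    aging_dbs_rate: float = 0.25  # DBS / year, background
    aging_id_rate: float = 2.5  # indels / year, background

    capox_cycles_range: tuple[int, int] = (1, 6)
    platinum_per_cycle_mean: float = 105.0
    platinum_per_cycle_sd: float = 33.0
    dbs_per_sbs: float = 1.0 / 26.0

    fiveFU_activation_prob: float = 0.3
    fiveFU_mean: float = 265.0
    fiveFU_sd: float = 195.0

    n_radio_donors: int = 2
    radio_id8_mean: float = 80.0
    radio_id8_sd: float = 15.0
    sv_del_per_id8: float = 0.18
    complex_sv_rate_radio: float = 2.0  # complex clusters per irradiated clone
    complex_sv_rate_background: float = 0.05

    vaf_clonal: tuple[float, float] = (60.0, 60.0)
    vaf_subclonal: tuple[float, float] = (4.0, 26.0)
    n_invitro_subclonal: int = 50

    seed: int | None = None

    def validate(self) -> None:
        mix_sum = sum(self.aging_mix.values())
        if not np.isclose(mix_sum, 1.0):
            raise ValueError(f"aging_mix proportions sum to {mix_sum}, not 1")
        for name in (
            "aging_rate_mean", "donor_sd", "residual_sd", "platinum_per_cycle_mean",
            "platinum_per_cycle_sd", "dbs_per_sbs", "fiveFU_mean", "fiveFU_sd",
            "radio_id8_mean", "radio_id8_sd", "sv_del_per_id8", "aging_dbs_rate",
            "aging_id_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fiveFU_activation_prob <= 1.0:
            raise ValueError("fiveFU_activation_prob must be a probability")
        if self.n_donors_treated > 0 and self.capox_cycles_range[1] < 1:
            raise ValueError("treated donors configured but zero chemotherapy cycles")
        q95 = stats.beta.ppf(0.95, *self.vaf_subclonal)
        if q95 >= 0.3:
            raise ValueError(
                f"subclonal VAF Beta{self.vaf_subclonal} has 95th percentile {q95:.3f} >= 0.3"
            )


@dataclass
class SimulatedCohort:
    """Metadata, mutation records, SV records and exact ground truth."""

    meta: pd.DataFrame
    records: pd.DataFrame | None
    sv_records: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig


def _trunc_round_normal(rng, mean: float, sd: float) -> int:
    return int(round(max(0.0, rng.normal(mean, sd))))


def _sbs_rows(rng, sid: str, n: int, profile: pd.Series, vaf_ab: tuple[float, float]):
    """Record rows for n SBS drawn multinomially from a signature profile."""
    chans = np.asarray(profile.index)
    counts = rng.multinomial(n, profile.to_numpy())
    rows = []
    for chan, k in zip(chans, counts):
        if k == 0:
            continue
        f5, sub, f3 = chan[0], chan[2:5], chan[6]
        ref, alt = _SBS_SUB[sub]
        for _ in range(k):
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": str(rng.integers(1, 23)),
                    "pos": int(rng.integers(10_000, 200_000_000)),
                    "ref": ref,
                    "alt": alt,
                    "mut_class": "SBS",
                    "vaf": float(rng.beta(*vaf_ab)),
                    "context": f5 + ref + f3,
                }
            )
    return rows


def _dbs_rows(rng, sid: str, n: int, profile: pd.Series, vaf_ab):
    counts = rng.multinomial(n, profile.to_numpy())
    rows = []
    for chan, k in zip(profile.index, counts):
        ref, alt = chan.split(">")
        for _ in range(k):
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": str(rng.integers(1, 23)),
                    "pos": int(rng.integers(10_000, 200_000_000)),
                    "ref": ref,
                    "alt": alt,
                    "mut_class": "DBS",
                    "vaf": float(rng.beta(*vaf_ab)),
                }
            )
    return rows


def _indel_alleles(rng, chan: str) -> tuple[str, str]:
    """Plausible VCF-style ref/alt for an ID83 channel (anchor base A)."""
    size_s, kind, motif_s, _ = chan.split(":")
    size = int(size_s)
    if motif_s in ("C", "T"):
        motif = motif_s
    else:
        motif = "".join(rng.choice(list("ACGT"), size=size))
    if kind == "Del":
        return "A" + motif, "A"
    return "A", "A" + motif


def _id_rows(rng, sid: str, n: int, profile: pd.Series, vaf_ab):
    counts = rng.multinomial(n, profile.to_numpy())
    rows = []
    for chan, k in zip(profile.index, counts):
        for _ in range(k):
            ref, alt = _indel_alleles(rng, chan)
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": str(rng.integers(1, 23)),
                    "pos": int(rng.integers(10_000, 200_000_000)),
                    "ref": ref,
                    "alt": alt,
                    "mut_class": "INDEL",
                    "vaf": float(rng.beta(*vaf_ab)),
                    "id_channel": chan,
                }
            )
    return rows


def _mixture_profile(reference: pd.DataFrame, mix: dict) -> pd.Series:
    p = sum(w * reference[name] for name, w in mix.items())
    return p / p.sum()


def simulate_cohort(
    config: CohortConfig | None = None,
    reference: dict[str, pd.DataFrame] | None = None,
    with_records: bool = True,
) -> SimulatedCohort:
    """Generate a synthetic cohort; fully reproducible under ``config.seed``.

    With ``with_records=False`` only metadata, SV records and the
    ground-truth count table are produced (fast path for burden-level
    simulation studies; per-mutation records are skipped).
    """
    config = config or CohortConfig()
    config.validate()
    reference = reference or synthetic_reference_set()
    for mt in ("SBS96", "DBS78", "ID83"):
        needed = set(config.aging_mix) if mt == "SBS96" else set()
        missing = needed - set(reference[mt].columns)
        if missing:
            raise ValueError(f"reference {mt} lacks signatures {sorted(missing)}")
    rng = np.random.default_rng(config.seed)

    sbs_ref, dbs_ref, id_ref = reference["SBS96"], reference["DBS78"], reference["ID83"]
    aging_sbs_profile = _mixture_profile(sbs_ref, config.aging_mix)
    aging_dbs_profile = _mixture_profile(
        dbs_ref, {s: 0.2 for s in ("DBS2", "DBS4", "DBS6", "DBS9", "DBS11")}
    )
    aging_id_profile = _mixture_profile(id_ref, {"ID1": 0.4, "ID2": 0.4, "ID5": 0.2})

    meta_rows, truth_rows, rec_rows, sv_rows = [], [], [], []

    donors = [("U%02d" % (i + 1), False) for i in range(config.n_donors_untreated)]
    donors += [("T%02d" % (i + 1), True) for i in range(config.n_donors_treated)]
    radio_donors = set()
    if config.n_donors_treated and config.n_radio_donors:
        treated_ids = [d for d, t in donors if t]
        radio_donors = set(
            rng.choice(treated_ids, size=min(config.n_radio_donors, len(treated_ids)), replace=False)
        )

    sv_counter = 0
    for donor_id, treated in donors:
        age = float(rng.uniform(*config.age_range))
        donor_eff = float(rng.normal(0.0, config.donor_sd))
        cycles = int(rng.integers(config.capox_cycles_range[0], config.capox_cycles_range[1] + 1)) if treated else 0
        radio = donor_id in radio_donors
        n_clones = config.clones_per_donor_treated if treated else config.clones_per_donor
        for c in range(n_clones):
            sid = f"{donor_id}_c{c + 1}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "donor_id": donor_id,
                    "tissue": config.tissue,
                    "age": age,
                    "capox_cycles": cycles,
                    "received_platinum": treated,
                    "received_5fu": treated,
                    "received_radiotherapy": radio,
                    "months_since_treatment": float(max(0.1, rng.normal(1.5, 0.8))) if treated else np.nan,
                }
            )

            aging = _trunc_round_normal(
                rng, config.aging_intercept + config.aging_rate_mean * age + donor_eff,
                config.residual_sd,
            )
            plat_sbs = 0
            if cycles > 0 and config.platinum_per_cycle_mean > 0:
                plat_sbs = _trunc_round_normal(
                    rng,
                    config.platinum_per_cycle_mean * cycles,
                    config.platinum_per_cycle_sd * np.sqrt(cycles),
                )
            plat_dbs = int(rng.binomial(plat_sbs, config.dbs_per_sbs)) if plat_sbs else 0
            fivefu = 0
            if treated and rng.random() < config.fiveFU_activation_prob:
                fivefu = _trunc_round_normal(rng, config.fiveFU_mean, config.fiveFU_sd)
            id8 = _trunc_round_normal(rng, config.radio_id8_mean, config.radio_id8_sd) if radio else 0
            radio_sv = int(rng.poisson(config.sv_del_per_id8 * id8)) if id8 else 0
            aging_dbs = int(rng.poisson(config.aging_dbs_rate * age))
            aging_id = int(rng.poisson(config.aging_id_rate * age))

            truth_rows.append(
                {
                    "sample_id": sid,
                    "donor_id": donor_id,
                    "aging": aging,
                    "platinum_sbs": plat_sbs,
                    "platinum_dbs": plat_dbs,
                    "fivefu": fivefu,
                    "radio_id8": id8,
                    "radio_sv": radio_sv,
                    "aging_dbs": aging_dbs,
                    "aging_id": aging_id,
                    "treated": treated,
                }
            )

            if with_records:
                vc = config.vaf_clonal
                rec_rows += _sbs_rows(rng, sid, aging, aging_sbs_profile, vc)
                if plat_sbs:
                    rec_rows += _sbs_rows(rng, sid, plat_sbs, sbs_ref["SBS35"], vc)
                if fivefu:
                    rec_rows += _sbs_rows(rng, sid, fivefu, sbs_ref["SBS17"], vc)
                if plat_dbs:
                    rec_rows += _dbs_rows(rng, sid, plat_dbs, dbs_ref["DBS5"], vc)
                if aging_dbs:
                    rec_rows += _dbs_rows(rng, sid, aging_dbs, aging_dbs_profile, vc)
                if aging_id:
                    rec_rows += _id_rows(rng, sid, aging_id, aging_id_profile, vc)
                if id8:
                    rec_rows += _id_rows(rng, sid, id8, id_ref["ID8"], vc)
                if config.n_invitro_subclonal:
                    rec_rows += _sbs_rows(
                        rng, sid, config.n_invitro_subclonal, aging_sbs_profile,
                        config.vaf_subclonal,
                    )

            # simple radiation deletions: 50 bp - 10 kb, no microhomology
            for _ in range(radio_sv):
                sv_counter += 1
                sv_rows.append(
                    {
                        "sample_id": sid,
                        "chrom": str(rng.integers(1, 23)),
                        "pos": int(rng.integers(10_000, 200_000_000)),
                        "sv_type": "DEL",
                        "sv_length": int(np.exp(rng.uniform(np.log(50), np.log(10_000)))),
                        "sv_cluster_size": 1,
                        "sv_cluster_id": f"cl{sv_counter}",
                        "sv_resolved_type": "DEL",
                        "microhomology_len": 0,
                    }
                )
            # complex clusters
            rate = config.complex_sv_rate_radio if radio else config.complex_sv_rate_background
            for _ in range(int(rng.poisson(rate))):
                sv_counter += 1
                ctype = str(rng.choice(["COMPLEX_SV", "COMPLEX_DEL", "RECIP_INV", "RECIP_TRANS"]))
                members = 2 if ctype.startswith("RECIP") else int(rng.integers(2, 5))
                for _ in range(members):
                    sv_rows.append(
                        {
                            "sample_id": sid,
                            "chrom": str(rng.integers(1, 23)),
                            "pos": int(rng.integers(10_000, 200_000_000)),
                            "sv_type": str(rng.choice(["DEL", "DUP", "INV", "TRA"])),
                            "sv_length": int(np.exp(rng.uniform(np.log(1_000), np.log(1_000_000)))),
                            "sv_cluster_size": members,
                            "sv_cluster_id": f"cl{sv_counter}",
                            "sv_resolved_type": ctype,
                            "microhomology_len": int(rng.integers(0, 6)),
                        }
                    )

    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    rec_cols = ["sample_id", "chrom", "pos", "ref", "alt", "mut_class", "vaf", "context", "id_channel"]
    if with_records:
        records = pd.DataFrame(rec_rows)
        for col in rec_cols:
            if col not in records.columns:
                records[col] = np.nan
        records = records[rec_cols]
    else:
        records = None
    sv_cols = ["sample_id", "chrom", "pos", "sv_type", "sv_length", "sv_cluster_size",
               "sv_cluster_id", "sv_resolved_type", "microhomology_len"]
    sv_records = pd.DataFrame(sv_rows, columns=sv_cols)
    return SimulatedCohort(meta=meta, records=records, sv_records=sv_records, truth=truth, config=config)


def burden_from_truth(truth: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Exact clonal burden table implied by the ground-truth counts.

    SBS = aging + platinum + 5-FU; DBS = background + platinum;
    INDEL = background + radiation ID8; SV = simple radiation deletions.
    (Subclonal spike-ins are excluded by construction, as the clonal
    filter would exclude them.)
    """
    t = truth.set_index("sample_id")
    m = meta.set_index("sample_id").loc[t.index]
    rows = []
    per_type = {
        "SBS": t["aging"] + t["platinum_sbs"] + t["fivefu"],
        "DBS": t["aging_dbs"] + t["platinum_dbs"],
        "INDEL": t["aging_id"] + t["radio_id8"],
        "SV": t["radio_sv"],
    }
    for mut_type, series in per_type.items():
        for sid, n in series.items():
            rows.append(
                {
                    "sample_id": sid,
                    "donor_id": m.loc[sid, "donor_id"],
                    "age": float(m.loc[sid, "age"]),
                    "tissue": m.loc[sid, "tissue"],
                    "mut_type": mut_type,
                    "burden": int(n),
                    "treated": bool(t.loc[sid, "treated"]),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path, format: str = "tsv") -> dict[str, Path]:
    """Write a cohort in the pipeline's own input formats.

    ``tsv`` emits a single mutation table with context columns; ``vcf``
    emits one VCF 4.2 per clone with VAF (AF), trinucleotide context (TNC)
    and indel channel (IDC) INFO fields.  Metadata and SV tables are
    always TSV.  The output round-trips losslessly through the catalog
    readers.
    """
    if cohort.records is None:
        raise ValueError("cohort was simulated without records")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta_path = out / "meta.tsv"
    cohort.meta.to_csv(meta_path, sep="\t", index=False)
    paths["meta"] = meta_path
    sv_path = out / "sv.tsv"
    cohort.sv_records.to_csv(sv_path, sep="\t", index=False)
    paths["sv"] = sv_path
    truth_path = out / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    if format == "tsv":
        mut_path = out / "mutations.tsv"
        cohort.records.to_csv(mut_path, sep="\t", index=False)
        paths["mutations"] = mut_path
    elif format == "vcf":
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for sid, sub in cohort.records.groupby("sample_id"):
            paths[f"vcf:{sid}"] = _write_vcf(sub, vcf_dir / f"{sid}.vcf")
        paths["vcf_dir"] = vcf_dir
    else:
        raise ValueError(f"unknown format {format!r}")
    return paths


def _write_vcf(records: pd.DataFrame, path: Path) -> Path:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for i in range(1, 23):
        header.contigs.add(str(i), length=250_000_000)
    header.info.add("AF", "A", "Float", "Variant allele frequency")
    header.info.add("TNC", 1, "String", "Raw-strand trinucleotide context (SBS)")
    header.info.add("IDC", 1, "String", "Pre-annotated ID83 channel (indels)")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        sub = records.sort_values(["chrom", "pos"], key=lambda s: s.astype(int) if s.name == "pos" else s.astype(str).str.zfill(2))
        for _, row in sub.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            rec.info["AF"] = float(row["vaf"])
            if isinstance(row.get("context"), str):
                rec.info["TNC"] = row["context"]
            if isinstance(row.get("id_channel"), str):
                rec.info["IDC"] = row["id_channel"]
            vf.write(rec)
    return path


def read_cohort(in_dir: str | Path, format: str = "tsv") -> SimulatedCohort:
    """Read back a written cohort through the catalog readers."""
    from . import catalog

    d = Path(in_dir)
    meta = catalog.read_meta(d / "meta.tsv")
    sv = catalog.read_sv_table(d / "sv.tsv")
    truth_path = d / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    if format == "tsv":
        records = catalog.read_mutations(d / "mutations.tsv", format="tsv")
    else:
        frames = [
            catalog.read_mutations(p, format="vcf") for p in sorted((d / "vcf").glob("*.vcf"))
        ]
        records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return SimulatedCohort(meta=meta, records=records, sv_records=sv, truth=truth, config=CohortConfig())
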
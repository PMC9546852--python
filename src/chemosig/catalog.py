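"""Somatic mutation catalogs: input parsing, clonal filtering, channel counting.

The in-memory convention is a pandas DataFrame of mutation records (one row
per somatic call) with columns::

    sample_id, chrom, pos, ref, alt, mut_class, vaf
    [context]      raw-strand trinucleotide flank5+ref+flank3 (SBS only)
    [id_channel]   pre-annotated ID83 channel (indels only)
    [sv_type, sv_length, sv_cluster_size, sv_resolved_type, microhomology_len]

Pre-annotated context columns let the pipeline run without a reference
genome; when a faidx-indexed FASTA is supplied, SBS flanks and indel windows
are fetched from it instead.

Mutation burden is the clonally filtered autosomal count per mutation type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import (
    channels_for,
    classify_dbs78,
    classify_id83,
    classify_sbs96,
)

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: INFO/FORMAT tag names tried in order when looking for a VAF annotation.
VAF_TAG_LADDER = ("PURPLE_AF", "AF", "VAF")

META_COLUMNS = [
    "sample_id",
    "donor_id",
    "tissue",
    "age",
    "capox_cycles",
    "received_platinum",
    "received_5fu",
    "received_radiotherapy",
    "months_since_treatment",
]

MUT_CLASSES = ("SBS", "DBS", "INDEL", "SV")


@dataclass
class MutationRecord:
    """One somatic variant in one clone."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_class: str
    vaf: float
    sv_type: str | None = None
    sv_length: int | None = None
    sv_cluster_size: int | None = None
    sv_resolved_type: str | None = None
    microhomology_len: int | None = None
    context: str | None = None
    id_channel: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.mut_class not in MUT_CLASSES:
            raise ValueError(f"unknown mut_class {self.mut_class!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.mut_class == "SBS" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("SBS requires single-base ref and alt")
        if self.mut_class == "DBS" and not (len(self.ref) == len(self.alt) == 2):
            raise ValueError("DBS requires two-base ref and alt")
        has_sv = any(
            v is not None
            for v in (self.sv_type, self.sv_length, self.sv_cluster_size, self.sv_resolved_type)
        )
        if (self.mut_class == "SV") != has_sv and self.mut_class == "SV":
            raise ValueError("SV record lacks SV annotations")
        if has_sv and self.mut_class != "SV":
            raise ValueError("SV annotations on a non-SV record")


@dataclass
class ContextMatrix:
    """Samples x channels count matrix for one channel scheme."""

    mut_type: str
    counts: pd.DataFrame  # index: sample_id, columns: channel labels

    def __post_init__(self) -> None:
        expected = list(channels_for(self.mut_type))
        if list(self.counts.columns) != expected:
            raise ValueError(f"columns do not match the {self.mut_type} channel order")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def burdens(self) -> pd.Series:
        """Per-sample total filtered burden of this mutation type."""
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, mut_type: str) -> "ContextMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(mut_type, df[list(channels_for(mut_type))])


def normalise_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix so chromosome names compare consistently."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def infer_mut_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SBS"
    if len(ref) == 2 and len(alt) == 2:
        return "DBS"
    return "INDEL"


def read_meta(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata table and validate its invariants."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS[:8] if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table lacks columns {missing}")
    for flag in ("received_platinum", "received_5fu", "received_radiotherapy"):
        meta[flag] = meta[flag].astype(bool)
    validate_meta(meta)
    return meta


def validate_meta(meta: pd.DataFrame) -> None:
    dup = meta["sample_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate sample_ids in metadata: {meta.loc[dup, 'sample_id'].tolist()}")
    bad = meta[(meta["capox_cycles"] > 0) & ~(meta["received_platinum"] & meta["received_5fu"])]
    if len(bad):
        raise ValueError(
            "capox_cycles > 0 implies received_platinum and received_5fu; "
            f"violated by samples {bad['sample_id'].tolist()}"
        )
    if (meta["age"] <= 0).any():
        raise ValueError("ages must be positive")


def read_mutations(
    path: str | Path,
    format: str = "tsv",
    sample_id: str | None = None,
    vaf_tag: str | None = None,
) -> pd.DataFrame:
    """Read somatic calls from a TSV table or a VCF into a records frame.

    TSV input carries ``sample_id, chrom, pos, ref, alt, vaf`` and optional
    ``context``/``id_channel`` columns.  VCF input (4.x, uncompressed or
    bgzipped) requires a VAF annotation: ``vaf_tag`` names the INFO or
    FORMAT field, otherwise a standard ladder of tag names is tried.
    Malformed allele strings are skipped with a logged warning count; a
    missing VAF is a hard error naming the record.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        needed = {"sample_id", "chrom", "pos", "ref", "alt", "vaf"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"mutation TSV lacks columns {sorted(missing)}")
        if "mut_class" not in df.columns:
            df["mut_class"] = [infer_mut_class(r, a) for r, a in zip(df["ref"], df["alt"])]
        df["chrom"] = df["chrom"].map(normalise_chrom)
        return df
    if format == "vcf":
        return _read_vcf(path, sample_id=sample_id, vaf_tag=vaf_tag)
    raise ValueError(f"unknown format {format!r}")


def _vaf_from_vcf_record(rec, vaf_tag: str | None) -> float | None:
    tags = (vaf_tag,) if vaf_tag else VAF_TAG_LADDER
    for tag in tags:
        if tag in rec.info:
            v = rec.info[tag]
            return float(v[0] if isinstance(v, tuple) else v)
    for tag in tags:
        for sample in rec.samples.values():
            if tag in sample and sample[tag] is not None:
                v = sample[tag]
                return float(v[0] if isinstance(v, tuple) else v)
    return None


def _read_vcf(path: str | Path, sample_id: str | None, vaf_tag: str | None) -> pd.DataFrame:
    import pysam

    sid = sample_id or Path(path).name.split(".vcf")[0]
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if alt.startswith("<") or not set(ref + alt) <= set("ACGTN"):
                skipped += 1
                continue
            if "N" in ref + alt:
                skipped += 1
                continue
            vaf = _vaf_from_vcf_record(rec, vaf_tag)
            if vaf is None:
                raise ValueError(
                    f"no VAF annotation on record {rec.chrom}:{rec.pos} {ref}>{alt} "
                    f"(tried tags {vaf_tag or VAF_TAG_LADDER})"
                )
            row = {
                "sample_id": sid,
                "chrom": normalise_chrom(rec.chrom),
                "pos": rec.pos,
                "ref": ref,
                "alt": alt,
                "mut_class": infer_mut_class(ref, alt),
                "vaf": vaf,
            }
            if "TNC" in rec.info:
                row["context"] = str(rec.info["TNC"])
            if "IDC" in rec.info:
                row["id_channel"] = str(rec.info["IDC"])
            rows.append(row)
    if skipped:
        logger.warning("skipped %d malformed/multi-allelic records in %s", skipped, path)
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "mut_class", "vaf"]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=cols)
    return df


def filter_clonal(
    records: pd.DataFrame,
    vaf_min: float = 0.30,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Keep clonal calls: VAF strictly above ``vaf_min``, autosomes only.

    The strict inequality follows the clonality cut used when reading out
    in-vivo mutations from clonally expanded stem cells: calls at or below
    30% VAF are treated as in-vitro (post clonal step) and discarded.
    Record order is preserved; the operation is idempotent.
    """
    if not 0.0 < vaf_min < 1.0:
        raise ValueError(f"vaf_min must be in (0, 1), got {vaf_min}")
    keep = records["vaf"] > vaf_min
    if autosomes_only:
        keep &= records["chrom"].map(normalise_chrom).isin(AUTOSOMES)
    return records.loc[keep]


def _sbs_channel(row: pd.Series, fasta) -> str:
    ctx = row.get("context")
    if isinstance(ctx, str) and len(ctx) == 3:
        return classify_sbs96(row["ref"], row["alt"], ctx[0], ctx[2])
    if fasta is None:
        raise ValueError(
            f"SBS record {row['chrom']}:{row['pos']} has no context column and no FASTA supplied"
        )
    chrom = _fasta_chrom(fasta, row["chrom"])
    seq = str(fasta[chrom][row["pos"] - 2 : row["pos"] + 1]).upper()
    return classify_sbs96(row["ref"], row["alt"], seq[0], seq[2])


def _indel_channel(row: pd.Series, fasta, window: int = 60) -> str:
    idc = row.get("id_channel")
    if isinstance(idc, str) and idc:
        return idc
    if fasta is None:
        raise ValueError(
            f"indel record {row['chrom']}:{row['pos']} has no id_channel column and no FASTA supplied"
        )
    chrom = _fasta_chrom(fasta, row["chrom"])
    start = max(0, row["pos"] - 1 - window)
    seq = str(fasta[chrom][start : row["pos"] + window]).upper()
    return classify_id83(row["ref"], row["alt"], seq, row["pos"] - 1 - start)


def _fasta_chrom(fasta, chrom: str) -> str:
    for cand in (chrom, f"chr{chrom}"):
        if cand in fasta:
            return cand
    raise KeyError(f"chromosome {chrom!r} not in FASTA")


def build_context_matrix(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    mut_type: str,
    fasta=None,
) -> ContextMatrix:
    """Count clonally filtered records into the channel scheme ``mut_type``.

    Rows follow metadata order; per-sample row sums equal that sample's
    filtered burden for the mutation type (count conservation).
    """
    chans = list(channels_for(mut_type))
    mclass = {"SBS96": "SBS", "DBS78": "DBS", "ID83": "INDEL"}[mut_type]
    sub = records[records["mut_class"] == mclass]
    unknown = set(sub["sample_id"]) - set(meta["sample_id"])
    if unknown:
        raise ValueError(f"samples in records missing from metadata: {sorted(unknown)}")
    counts = pd.DataFrame(
        0, index=pd.Index(meta["sample_id"], name="sample_id"), columns=chans, dtype=int
    )
    if len(sub):
        labels = _channel_labels(sub, mut_type, fasta)
        tab = pd.crosstab(sub["sample_id"].to_numpy(), labels)
        counts.loc[tab.index, tab.columns] += tab.astype(int)
    return ContextMatrix(mut_type, counts.astype(int))


def _channel_labels(sub: pd.DataFrame, mut_type: str, fasta) -> np.ndarray:
    refs = sub["ref"].to_numpy()
    alts = sub["alt"].to_numpy()
    if mut_type == "DBS78":
        return np.array([classify_dbs78(r, a) for r, a in zip(refs, alts)])
    ctx = sub["context"].to_numpy() if "context" in sub.columns else np.full(len(sub), None)
    idc = sub["id_channel"].to_numpy() if "id_channel" in sub.columns else np.full(len(sub), None)
    out = []
    for i in range(len(sub)):
        if mut_type == "SBS96":
            c = ctx[i]
            if isinstance(c, str) and len(c) == 3:
                out.append(classify_sbs96(refs[i], alts[i], c[0], c[2]))
            else:
                out.append(_sbs_channel(sub.iloc[i], fasta))
        else:
            c = idc[i]
            if isinstance(c, str) and c:
                out.append(c)
            else:
                out.append(_indel_channel(sub.iloc[i], fasta))
    return np.array(out)


def burden_table(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-mutation-type burden table from filtered records.

    Returns rows (sample_id, donor_id, age, tissue, mut_type, burden,
    treated); burden for SV counts simple events only where cluster
    annotations are present, otherwise all SV records.
    """
    rows = []
    by_sample = dict(tuple(records.groupby("sample_id"))) if len(records) else {}
    for _, m in meta.iterrows():
        sub = by_sample.get(m["sample_id"])
        treated = bool(m["received_platinum"] or m["received_5fu"] or m["received_radiotherapy"])
        for mut_type, mclass in (("SBS", "SBS"), ("DBS", "DBS"), ("INDEL", "INDEL"), ("SV", "SV")):
            if sub is None:
                n = 0
            else:
                cls = sub[sub["mut_class"] == mclass]
                if mclass == "SV" and "sv_cluster_size" in cls.columns and len(cls):
                    simple = cls[
                        (cls["sv_cluster_size"].fillna(1) == 1)
                        & cls["sv_resolved_type"].isin(["DEL", "DUP"])
                    ]
                    n = len(simple)
                else:
                    n = len(cls)
            rows.append(
                {
                    "sample_id": m["sample_id"],
                    "donor_id": m["donor_id"],
                    "age": float(m["age"]),
                    "tissue": m["tissue"],
                    "mut_type": mut_type,
                    "burden": int(n),
                    "treated": treated,
                }
            )
    return pd.DataFrame(rows)


def read_sv_table(path: str | Path) -> pd.DataFrame:
    """Read an SV table (one row per breakpoint cluster member)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"sample_id", "chrom", "pos", "sv_type", "sv_length", "sv_cluster_size", "sv_resolved_type"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"SV table lacks columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalise_chrom)
    return df
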
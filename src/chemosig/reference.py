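"""Synthetic reference signature profiles.

These are *synthetic*, stylised stand-ins for the COSMIC reference
catalogue, generated deterministically at import time: each profile
concentrates its mass on the channel block characteristic of the process it
emulates (e.g. the platinum doublet signature on CT>AA / CT>AC, the
radiation indel signature on >=5 bp deletions without microhomology, the
5-FU substitution signature on T>G channels) plus a small broad floor.
They reproduce the *structure* the pipeline relies on — near-orthogonal,
channel-resolved processes — without shipping any third-party data, and are
the default reference set for tests and simulations.  Analyses of real
cohorts should load genuine reference matrices via
:func:`load_reference_tsv` (channels x signatures TSV in canonical channel
order).
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import channels_for

# mass placed on the characteristic channel block; the remainder is a broad
# Dirichlet floor over all channels
_BLOCK_MASS = 0.95


def _sbs_block(sub: str, flank5: str | None = None, flank3: str | None = None) -> list[str]:
    return [
        c
        for c in channels_for("SBS96")
        if c[2:5] == sub
        and (flank5 is None or c[0] in flank5)
        and (flank3 is None or c[6] in flank3)
    ]


def _dbs_block(refs: tuple[str, ...]) -> list[str]:
    return [c for c in channels_for("DBS78") if c[:2] in refs]


def _id_block(prefixes: tuple[str, ...]) -> list[str]:
    return [c for c in channels_for("ID83") if c.startswith(prefixes)]


# disjoint channel blocks keep the synthetic set near-orthogonal, so that
# attribution error in tests reflects the method rather than profile overlap
_SBS_BLOCKS = {
    "SBS1": _sbs_block("C>T", flank3="G"),  # deamination at methyl-CpG
    "SBS5": _sbs_block("C>T", flank3="ACT") + _sbs_block("T>C"),  # clock-like background
    "SBS18": _sbs_block("C>A"),  # oxidative damage
    "SBS17": _sbs_block("T>G"),  # 5-FU (17a+17b merged)
    "SBS35": _sbs_block("C>G"),  # platinum
    "SBS88": _sbs_block("T>A"),  # colibactin
}

_DBS_BLOCKS = {
    "DBS2": _dbs_block(("CC",)),
    "DBS4": _dbs_block(("TC",)),
    "DBS5": ["CT>AA", "CT>AC"] + _dbs_block(("CT",)),  # platinum doublets
    "DBS6": _dbs_block(("TG",)),
    "DBS9": _dbs_block(("TT",)),
    "DBS11": _dbs_block(("GC", "AC")),
}

_ID_BLOCKS = {
    "ID1": _id_block(("1:Ins:T",)),  # T homopolymer slippage insertions
    "ID2": _id_block(("1:Del:T",)),  # T homopolymer slippage deletions
    "ID5": _id_block(("1:Del:C", "1:Ins:C")),
    "ID8": ["5:Del:R:0", "4:Del:R:0", "3:Del:R:0"]
    + _id_block(("5:Del:M",)),  # NHEJ: >=5 bp deletions, little/no microhomology
    "ID18": _id_block(("2:Ins:R", "2:Del:R")),  # colibactin-like
}

_BLOCKS = {"SBS96": _SBS_BLOCKS, "DBS78": _DBS_BLOCKS, "ID83": _ID_BLOCKS}


def _profile(mut_type: str, name: str, block: list[str]) -> pd.Series:
    block = list(dict.fromkeys(block))  # dedupe, order-preserving
    chans = list(channels_for(mut_type))
    rng = np.random.default_rng(zlib.crc32(f"{mut_type}:{name}".encode()))
    floor = rng.dirichlet(np.full(len(chans), 2.0))
    p = pd.Series((1 - _BLOCK_MASS) * floor, index=chans)
    # heavier weight on the first listed channels so hallmark peaks stand out
    w = rng.dirichlet(np.linspace(6.0, 1.5, len(block)))
    p.loc[block] = p.loc[block].to_numpy() + _BLOCK_MASS * w
    return p / p.sum()


def synthetic_signatures(mut_type: str) -> pd.DataFrame:
    """Deterministic synthetic reference set (channels x signatures)."""
    blocks = _BLOCKS[mut_type]
    out = pd.DataFrame({name: _profile(mut_type, name, blk) for name, blk in blocks.items()})
    out.index = pd.Index(channels_for(mut_type), name="channel")
    return out


def synthetic_reference_set() -> dict[str, pd.DataFrame]:
    """Synthetic signature matrices for all three channel schemes."""
    return {mt: synthetic_signatures(mt) for mt in ("SBS96", "DBS78", "ID83")}


def load_reference_tsv(path: str | Path, mut_type: str) -> pd.DataFrame:
    """Load a channels x signatures reference matrix from TSV.

    The first column must hold channel labels; they are reordered to the
    canonical channel order and columns are renormalised to sum to 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    chans = list(channels_for(mut_type))
    missing = set(chans) - set(df.index)
    if missing:
        raise ValueError(f"reference matrix lacks {len(missing)} {mut_type} channels")
    df = df.loc[chans]
    return df / df.sum(axis=0)
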
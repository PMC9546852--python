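"""Canonical mutation-type channel schemes and classifiers.

Implements the three standard signature-analysis channel schemes:

* SBS96 — single base substitutions in trinucleotide context, collapsed to
  the pyrimidine strand (6 substitution classes x 4 x 4 flanks).
* DBS78 — doublet base substitutions collapsed by reverse complement to the
  10 canonical reference doublets.
* ID83 — small insertions/deletions classified by type, length, local
  repeat count and (for non-repetitive deletions) breakpoint microhomology.

Channel label formats follow the COSMIC conventions used across the
signature literature: ``A[C>T]G``, ``CT>AA`` and ``1:Del:T:3``.
"""

from __future__ import annotations

from functools import lru_cache

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

#: Canonical reference doublets for the DBS78 scheme.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")

# Alt doublets per canonical reference, in canonical COSMIC order.  The four
# palindromic references (AT, CG, GC, TA) keep only one member of each
# reverse-complement alt pair.
_DBS_ALTS = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (upper-case ACGT only)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _check_base(b: str, what: str) -> None:
    if b not in COMPLEMENT:
        raise ValueError(f"{what} must be one of A/C/G/T, got {b!r}")


@lru_cache(maxsize=1)
def sbs96_channels() -> tuple[str, ...]:
    """The 96 SBS channels in canonical order (substitution-major)."""
    subs = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    return tuple(
        f"{f5}[{sub}]{f3}" for sub in subs for f5 in "ACGT" for f3 in "ACGT"
    )


@lru_cache(maxsize=1)
def dbs78_channels() -> tuple[str, ...]:
    """The 78 DBS channels in canonical order."""
    return tuple(
        f"{ref}>{alt}" for ref in DBS_CANONICAL_REFS for alt in _DBS_ALTS[ref]
    )


@lru_cache(maxsize=1)
def id83_channels() -> tuple[str, ...]:
    """The 83 indel channels in canonical order.

    The trailing integer is the COSMIC machine label: for deletions it is
    (number of repeat units including the deleted copy) - 1 capped at 5; for
    insertions it is the pre-existing repeat count capped at 5; for
    microhomology deletions it is the microhomology length capped at 5.
    """
    chans: list[str] = []
    for kind in ("Del", "Ins"):
        for base in ("C", "T"):
            chans += [f"1:{kind}:{base}:{n}" for n in range(6)]
    for kind in ("Del", "Ins"):
        for size in (2, 3, 4, 5):
            chans += [f"{size}:{kind}:R:{n}" for n in range(6)]
    # Re-order to the canonical layout: 1bp del, 1bp ins, >1bp del repeats,
    # >1bp ins repeats, then microhomology deletions.
    chans = (
        [f"1:Del:{b}:{n}" for b in "CT" for n in range(6)]
        + [f"1:Ins:{b}:{n}" for b in "CT" for n in range(6)]
        + [f"{s}:Del:R:{n}" for s in (2, 3, 4, 5) for n in range(6)]
        + [f"{s}:Ins:R:{n}" for s in (2, 3, 4, 5) for n in range(6)]
        + ["2:Del:M:1"]
        + [f"3:Del:M:{n}" for n in (1, 2)]
        + [f"4:Del:M:{n}" for n in (1, 2, 3)]
        + [f"5:Del:M:{n}" for n in (1, 2, 3, 4, 5)]
    )
    assert len(chans) == 83
    return tuple(chans)


def channels_for(mut_type: str) -> tuple[str, ...]:
    """Channel list for a scheme name (``SBS96``, ``DBS78`` or ``ID83``)."""
    try:
        return {"SBS96": sbs96_channels, "DBS78": dbs78_channels, "ID83": id83_channels}[
            mut_type
        ]()
    except KeyError:
        raise ValueError(f"unknown mutation-type scheme {mut_type!r}") from None


def classify_sbs96(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Trinucleotide-context channel of a single base substitution.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand, swapping and complementing the flanks accordingly.
    """
    for b, what in ((ref, "ref"), (alt, "alt"), (flank5, "flank5"), (flank3, "flank3")):
        _check_base(b, what)
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


@lru_cache(maxsize=1)
def _dbs_lookup() -> dict[tuple[str, str], str]:
    table: dict[tuple[str, str], str] = {}
    for ref in DBS_CANONICAL_REFS:
        for alt in _DBS_ALTS[ref]:
            label = f"{ref}>{alt}"
            table[(ref, alt)] = label
            table[(revcomp(ref), revcomp(alt))] = label
    return table


def classify_dbs78(ref2: str, alt2: str) -> str:
    """Canonical DBS78 channel of a doublet substitution.

    Both positions must change (single-position differences are SBS calls
    mis-labelled as doublets upstream and are rejected).
    """
    if len(ref2) != 2 or len(alt2) != 2:
        raise ValueError("doublets must be length-2 strings")
    for b in ref2 + alt2:
        _check_base(b, "doublet base")
    if ref2 == alt2:
        raise ValueError("ref and alt doublets are identical")
    if ref2[0] == alt2[0] or ref2[1] == alt2[1]:
        raise ValueError(
            f"{ref2}>{alt2} changes only one position; not a doublet substitution"
        )
    return _dbs_lookup()[(ref2, alt2)]


def _run_length(seq: str, start: int, step: int, motif: str) -> tuple[int, bool]:
    """Contiguous copies of ``motif`` walking from ``start``.

    Returns (count, truncated): ``truncated`` is True when the run was still
    matching at the window edge, i.e. the window may undercount.
    """
    k = len(motif)
    count = 0
    i = start
    while True:
        if i < 0 or i + k > len(seq):
            return count, True
        if seq[i : i + k] != motif:
            return count, False
        count += 1
        i += step * k


def classify_id83(ref: str, alt: str, local_sequence: str, offset: int) -> str:
    """ID83 channel of an indel given its local sequence context.

    ``ref``/``alt`` follow VCF convention (shared anchor base first).
    ``local_sequence`` is reference sequence containing the event;
    ``offset`` is the 0-based index of the anchor base within it.  The
    window must extend far enough that no repeat run is cut off before the
    6-unit class cap; otherwise an error names the required window.

    Repeat units are counted contiguously on both sides of the indel;
    microhomology is evaluated only for deletions of >= 2 bp with zero
    additional repeat copies.
    """
    if len(ref) == len(alt):
        raise ValueError("not an indel: ref and alt have equal length")
    if len(ref) > 1 and len(alt) > 1:
        raise ValueError("complex indel (both sides > 1 bp) is not classifiable")
    seq = local_sequence.upper()
    is_del = len(ref) > len(alt)
    motif = (ref[1:] if is_del else alt[1:]).upper()
    d = len(motif)
    if d == 0:
        raise ValueError("empty indel allele")
    if is_del and seq[offset + 1 : offset + 1 + d] != motif:
        raise ValueError(
            f"deleted allele {motif} does not match local_sequence at offset {offset}"
        )

    left, ltrunc = _run_length(seq, offset + 1 - d, -d, motif)
    if is_del:
        right, rtrunc = _run_length(seq, offset + 1 + d, d, motif)
    else:
        right, rtrunc = _run_length(seq, offset + 1, d, motif)
    copies = left + right  # additional full copies besides the event itself
    if copies < 6 and (ltrunc or rtrunc):
        raise ValueError(
            f"local_sequence window too small: repeat run of {motif!r} reaches the "
            f"window edge before the 6-unit cap; supply >= {7 * d} bp of flank"
        )

    size_label = min(d, 5)
    if d == 1:
        base = motif if motif in PYRIMIDINES else COMPLEMENT[motif]
        if is_del:
            return f"1:Del:{base}:{min(copies + 1, 6) - 1}"
        return f"1:Ins:{base}:{min(copies, 5)}"

    if not is_del:
        return f"{size_label}:Ins:R:{min(copies, 5)}"
    if copies > 0:
        return f"{size_label}:Del:R:{min(copies + 1, 6) - 1}"

    # repeat-free deletion: measure breakpoint microhomology
    del_start = offset + 1
    del_end = del_start + d
    mh_right = 0
    while (
        mh_right < d - 1
        and del_end + mh_right < len(seq)
        and seq[del_end + mh_right] == motif[mh_right]
    ):
        mh_right += 1
    mh_left = 0
    while (
        mh_left < d - 1
        and del_start - 1 - mh_left >= 0
        and seq[del_start - 1 - mh_left] == motif[d - 1 - mh_left]
    ):
        mh_left += 1
    mh = max(mh_left, mh_right)
    if mh == 0:
        return f"{size_label}:Del:R:0"
    return f"{size_label}:Del:M:{min(mh, 5)}"
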
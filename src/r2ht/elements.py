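"""Structural characterization of R2-like retroelement sequences.

R2 non-LTR retrotransposons carry a single long ORF flanked by 5' and 3'
UTRs and end in a 3' poly-(A) tail.  Decayed genomic copies accumulate
frameshifts (1-bp indels that split the ORF across reading frames),
premature stop codons, large deletions and tandem duplications.  This
module trims poly-A tails, finds ORFs (joining frame-shifted and
read-through segments), translates them, scans the N-terminal region of
the protein for zinc-finger motifs (whose number and configuration
diagnose the R2-A/-B/-C/-D clades), and annotates large structural
variants against a reference copy.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

GAP = "-"
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Zinc-finger motif patterns (C2H2 consensus and its CCHC variant).
#: Overridable by passing ``patterns`` to :func:`detect_zinc_fingers`.
ZF_PATTERNS = {
    "CCHH": r"C.{2,4}C.{8,16}H.{3,5}H",
    "CCHC": r"C.{2,4}C.{8,16}H.{3,5}C",
}

#: Clade suggested by the ordered motif configuration at the N-terminus.
ZF_CLADES = {
    ("CCHH",): "R2-D",
    ("CCHC", "CCHH"): "R2-B",
}


class InvalidInputError(ValueError):
    """Raised on gapped/empty input where ungapped sequence is required."""


class InvalidAlignmentError(ValueError):
    """Raised when paired alignment rows have unequal lengths."""


@dataclass
class ElementRecord:
    """One element copy (or lineage consensus) tied to a host taxon.

    ``aligned_start``/``aligned_end`` give the 1-based inclusive columns of
    the master alignment covered by this record; partial copies (e.g. a
    5'-only fragment) cover a sub-interval.
    """

    id: str
    host_taxon: str
    seq: str
    is_fragment: bool = False
    aligned_start: int = 1
    aligned_end: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidInputError(f"record {self.id!r} has empty sequence")
        if self.aligned_end is None:
            self.aligned_end = self.aligned_start + len(self.seq) - 1
        if self.aligned_start > self.aligned_end:
            raise InvalidInputError(
                f"record {self.id!r}: aligned_start > aligned_end"
            )

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass
class OrfAnnotation:
    """An ORF, possibly pieced together across frameshifts.

    ``length_nt`` spans ``start``..``end`` inclusive (terminal stop codon
    included); for a clean single-frame ORF ``protein_length_aa`` equals
    ``length_nt/3 - 1``.  ``frameshift_positions`` are the 1-based
    nucleotide positions where the reading frame changes (the midpoint of
    the ambiguity window; see ``frameshift_windows``);
    ``internal_stop_positions`` are in-frame stops retained inside the
    joined ORF (read-through).

    A frameshift caused by a 1-bp indel cannot be localized exactly from
    a single sequence: both the old and the new frame are open throughout
    the interval between the new frame's opening and the old frame's
    terminal stop.  ``frameshift_windows`` records that (lo, hi) interval
    per joint; the true indel site lies inside it.
    """

    start: int
    end: int
    frameshift_positions: list[int] = field(default_factory=list)
    frameshift_windows: list[tuple[int, int]] = field(default_factory=list)
    internal_stop_positions: list[int] = field(default_factory=list)
    protein: str = ""

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def protein_length_aa(self) -> int:
        return len(self.protein)


@dataclass
class ZincFingerProfile:
    motifs: list[str]
    spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.motifs)

    @property
    def clade_suggestion(self) -> str | None:
        return ZF_CLADES.get(tuple(self.motifs))


@dataclass(frozen=True)
class StructuralVariant:
    """A large indel relative to a reference copy.

    ``kind`` is one of ``deletion``, ``insertion`` or ``duplication``
    (a duplication is an insertion whose sequence tandemly repeats the
    adjacent block).  Coordinates are 1-based inclusive on the ungapped
    reference; for insertions ``ref_start == ref_end`` marks the reference
    position immediately preceding the inserted block and ``length_bp`` is
    the inserted length.
    """

    kind: str
    ref_start: int
    ref_end: int
    length_bp: int


def _check_ungapped(seq: str) -> str:
    if not seq:
        raise InvalidInputError("empty sequence")
    if GAP in seq:
        raise InvalidInputError("gapped sequence where ungapped is required")
    return seq.upper()


def trim_poly_a(seq: str, min_run: int = 5) -> tuple[str, int]:
    """Trim the 3' terminal poly-(A) run.

    The tail is trimmed only when the terminal A-run is at least
    ``min_run`` nucleotides, which avoids clipping biological A's;
    genuine R2 tails run 7-9 nt.  Returns ``(trimmed, tail_length)``.
    """
    seq = _check_ungapped(seq)
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    tail = n - i
    if tail >= min_run:
        return seq[:i], tail
    return seq, 0


def _stop_free_runs(seq: str, frame: int) -> list[dict]:
    """Maximal stop-free codon runs in one forward frame.

    ``run_start`` is the 1-based start of the run, ``atg_start`` the
    1-based position of the first ATG inside it (or None), ``end`` the
    1-based end including the terminating stop codon when one exists,
    ``stop_at`` the 1-based first position of that stop.
    """
    runs = []
    n = len(seq)
    run_start = frame  # 0-based
    atg = None
    pos = frame
    while pos + 3 <= n:
        codon = seq[pos:pos + 3]
        if codon in STOP_CODONS:
            if pos > run_start or atg is not None:
                runs.append({
                    "run_start": run_start + 1,
                    "atg_start": None if atg is None else atg + 1,
                    "end": pos + 3,
                    "frame": frame,
                    "stop_at": pos + 1,
                })
            run_start = pos + 3
            atg = None
        elif codon == "ATG" and atg is None:
            atg = pos
        pos += 3
    if pos > run_start:
        runs.append({
            "run_start": run_start + 1,
            "atg_start": None if atg is None else atg + 1,
            "end": pos,
            "frame": frame,
            "stop_at": None,
        })
    return runs


def find_orf(
    seq: str,
    min_segment: int = 300,
    max_join_gap: int = 30,
    max_internal_stops: int = 2,
) -> OrfAnnotation | None:
    """Find the longest (possibly frameshift-joined) ORF.

    All three forward frames are scanned for stop-free codon runs.  A
    chain starts at an ATG-initiated run of at least ``min_segment`` bp
    and extends by joining further runs: a run in a *different* frame
    joins when it starts no more than ``max_join_gap`` bp after the
    upstream run's end (overlap allowed — a frameshift by deletion makes
    the two reading frames overlap), recording a frameshift; the run
    continuing in the *same* frame immediately after a stop codon joins
    by read-through, recording an internal stop.  At most
    ``max_internal_stops`` retained stops are tolerated per ORF.  The
    chain maximizing the joined span wins; a join must lengthen the ORF
    beyond both partners.

    Returns ``None`` when no qualifying start segment exists (a no-ORF
    result, not an error).
    """
    seq = _check_ungapped(seq)
    runs = []
    for frame in range(3):
        runs.extend(_stop_free_runs(seq, frame))
    # every chain segment, not only the starter, must clear min_segment:
    # joining short incidental off-frame runs would pad the ORF with
    # non-coding sequence
    runs = [r for r in runs
            if r["end"] - r["run_start"] + 1 >= min_segment]
    runs.sort(key=lambda s: (s["run_start"], s["end"]))
    n = len(runs)

    def seg_len(s):
        base = s["atg_start"] if s["atg_start"] else s["run_start"]
        return s["end"] - base + 1

    starters = [
        i for i, s in enumerate(runs)
        if s["atg_start"] is not None and s["end"] - s["atg_start"] + 1
        >= min_segment
    ]
    if not starters:
        return None

    # state[j] = (chain_start, n_shifts, n_stops) of the best chain ending
    # at run j: minimal start (maximal span), then fewest frameshifts,
    # then fewest retained stops.
    state: list[tuple[int, int, int] | None] = [None] * n
    prev = [-1] * n
    for i in starters:
        state[i] = (runs[i]["atg_start"], 0, 0)
    for j in range(n):
        for i in range(j):
            if state[i] is None:
                continue
            a, b = runs[i], runs[j]
            if b["end"] <= a["end"]:
                continue
            start_i, shifts_i, stops_i = state[i]
            if a["frame"] != b["frame"]:
                if b["run_start"] - a["end"] > max_join_gap:
                    continue
                cand = (start_i, shifts_i + 1, stops_i)
            else:
                if a["stop_at"] is None or b["run_start"] != a["end"] + 1:
                    continue
                if stops_i + 1 > max_internal_stops:
                    continue
                cand = (start_i, shifts_i, stops_i + 1)
            span = b["end"] - start_i + 1
            if span <= seg_len(a) or span <= seg_len(b):
                continue
            if state[j] is None or cand < state[j]:
                state[j] = cand
                prev[j] = i

    best = max(
        (j for j in range(n) if state[j] is not None),
        key=lambda j: (
            runs[j]["end"] - state[j][0] + 1, -state[j][1], -state[j][2],
        ),
    )
    chain = []
    j = best
    while j >= 0:
        chain.append(runs[j])
        j = prev[j]
    chain.reverse()

    stops = [
        a["stop_at"]
        for a, b in zip(chain, chain[1:])
        if a["frame"] == b["frame"] and a["stop_at"] is not None
    ]

    shifts: list[int] = []
    windows: list[tuple[int, int]] = []
    for a, b in zip(chain, chain[1:]):
        if a["frame"] == b["frame"]:
            continue
        lo = max(b["run_start"], a["run_start"])
        hi = a["end"]
        windows.append((lo, hi))
        shifts.append((lo + hi) // 2)

    start = chain[0]["atg_start"]
    orf = OrfAnnotation(
        start=start,
        end=chain[-1]["end"],
        frameshift_positions=shifts,
        frameshift_windows=windows,
        internal_stop_positions=sorted(stops),
    )
    orf.protein = _translate_chain(seq, chain, shifts)
    return orf


def _translate_chain(seq: str, chain: list[dict], shifts: list[int]) -> str:
    """Piecewise translation: each piece read in its own frame, switching
    at the estimated frameshift joint."""
    parts = []
    shift_iter = iter(shifts)
    cursor = chain[0]["atg_start"] - 1  # 0-based
    for k, s in enumerate(chain):
        nxt = chain[k + 1] if k + 1 < len(chain) else None
        if nxt is not None and nxt["frame"] != s["frame"]:
            joint = next(shift_iter) - 1
            end = max(cursor, joint)
        else:
            end = s["end"]
        sub = seq[cursor:end]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate())
        parts.append(aa)
        if nxt is not None:
            if nxt["frame"] != s["frame"]:
                # resume at the first position >= end in the new frame
                cursor = end + ((nxt["frame"] - end) % 3)
            else:
                cursor = nxt["run_start"] - 1
    aa = "".join(parts)
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def translate_orf(seq: str, orf: OrfAnnotation) -> str:
    """Translate a clean (zero-frameshift) ORF with the standard code.

    The terminal stop is excluded from the protein.  Raises
    :class:`InvalidInputError` when a zero-frameshift ORF length is not
    divisible by 3 (an internal inconsistency).  Frameshifted ORFs carry
    their piecewise translation in ``orf.protein`` already.
    """
    seq = _check_ungapped(seq)
    if orf.frameshift_positions:
        return orf.protein
    if orf.length_nt % 3 != 0:
        raise InvalidInputError(
            f"ORF length {orf.length_nt} not divisible by 3"
        )
    aa = str(Seq(seq[orf.start - 1:orf.end]).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    orf.protein = aa
    return aa


def detect_zinc_fingers(
    protein: str,
    window: int = 250,
    patterns: dict[str, str] | None = None,
) -> ZincFingerProfile:
    """Scan the protein N-terminus for zinc-finger motifs.

    Non-overlapping matches of the configured patterns within the first
    ``window`` residues, reported in N→C order.  One CCHH suggests clade
    R2-D; CCHC followed by CCHH suggests R2-B.
    """
    if not protein:
        raise InvalidInputError("empty protein")
    patterns = patterns or ZF_PATTERNS
    region = protein[:window]
    hits: list[tuple[int, int, str]] = []
    for name, pat in patterns.items():
        for m in re.finditer(pat, region):
            hits.append((m.start(), m.end(), name))
    hits.sort()
    chosen: list[tuple[int, int, str]] = []
    for h in hits:
        if all(h[0] >= c[1] or h[1] <= c[0] for c in chosen):
            chosen.append(h)
    chosen.sort()
    return ZincFingerProfile(
        motifs=[name for _, _, name in chosen],
        spans=[(s + 1, e) for s, e, _ in chosen],
    )


def _ungapped_pos(row: str, col: int) -> int:
    """1-based ungapped position of alignment column ``col`` (0-based)."""
    return len(row[:col + 1].replace(GAP, ""))


def annotate_structural_variants(
    query_aligned: str,
    reference_aligned: str,
    l_min: int = 50,
    duplication_identity: float = 0.9,
) -> list[StructuralVariant]:
    """Annotate large indels of a query against a reference copy.

    The two rows must come pre-aligned (gaps encode the indels).  Gap
    runs of at least ``l_min`` bp in the query are deletions; gap runs in
    the reference are insertions, reclassified as (tandem) duplications
    when the inserted query block repeats its upstream or downstream
    query neighbourhood at >= ``duplication_identity`` identity.
    Coordinates are 1-based inclusive on the ungapped reference.
    """
    q, r = query_aligned.upper(), reference_aligned.upper()
    if len(q) != len(r):
        raise InvalidAlignmentError(
            f"aligned rows differ in length ({len(q)} vs {len(r)})"
        )
    variants: list[StructuralVariant] = []
    for row, other, is_del in ((q, r, True), (r, q, False)):
        for m in re.finditer(rf"{GAP}{{{l_min},}}", row):
            a, b = m.start(), m.end()
            if other[a:b].count(GAP) == b - a:
                continue  # gap in both rows: not an indel between this pair
            length = (b - a) - other[a:b].count(GAP)
            if length < l_min:
                continue
            if is_del:
                variants.append(StructuralVariant(
                    kind="deletion",
                    ref_start=_ungapped_pos(r, a),
                    ref_end=_ungapped_pos(r, b - 1),
                    length_bp=length,
                ))
            else:
                inserted = other[a:b].replace(GAP, "")
                anchor = _ungapped_pos(r, a - 1) if a > 0 else 0
                kind = "insertion"
                up = other[:a].replace(GAP, "")[-length:]
                down = other[b:].replace(GAP, "")[:length]
                for flank in (up, down):
                    if len(flank) == length and _identity(inserted, flank) \
                            >= duplication_identity:
                        kind = "duplication"
                        break
                variants.append(StructuralVariant(
                    kind=kind,
                    ref_start=max(anchor, 1),
                    ref_end=max(anchor, 1),
                    length_bp=length,
                ))
    variants.sort(key=lambda v: (v.ref_start, v.ref_end))
    return variants


def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def characterize(record: ElementRecord, min_segment: int = 300) -> dict:
    """Full single-element annotation (one record per element).

    Mirrors the schematic fields of a structural map: trimmed length,
    poly-A tail, ORF span and disruptions, protein length, zinc-finger
    motifs and suggested clade.
    """
    trimmed, tail = trim_poly_a(record.ungapped)
    orf = find_orf(trimmed, min_segment=min_segment)
    out = {
        "id": record.id,
        "host_taxon": record.host_taxon,
        "length_bp": len(trimmed),
        "poly_a_tail": tail,
        "is_fragment": record.is_fragment,
    }
    if orf is None:
        out.update(orf_found=False)
        return out
    out.update(
        orf_found=True,
        orf_start=orf.start,
        orf_end=orf.end,
        orf_length_nt=orf.length_nt,
        n_frameshifts=len(orf.frameshift_positions),
        frameshift_positions=orf.frameshift_positions,
        n_internal_stops=len(orf.internal_stop_positions),
        internal_stop_positions=orf.internal_stop_positions,
        protein_length_aa=orf.protein_length_aa,
    )
    if orf.protein:
        zf = detect_zinc_fingers(orf.protein)
        out.update(
            zinc_fingers=zf.motifs,
            clade_suggestion=zf.clade_suggestion,
        )
    return out
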
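"""Profile hidden Markov model construction and homeodomain scanning.

A profile HMM is estimated from an aligned set of ~60-residue homeodomains
(match/insert/delete architecture, log2-odds emissions against a background
estimated from the same alignment) and used to find local, gapped matches in
six-frame translations of genomic DNA.  The search is a Smith-Waterman-style
local Viterbi: the maximum-scoring alignment of any peptide substring to any
consecutive run of match states, reported in bits.

Two scoring conventions matter downstream:

* In-frame stop codons (``'*'``) are not forbidden but emitted at a large
  negative constant (-20 bits) by every state, match and insert alike, so a
  single stop inside a homeobox penalizes — but usually does not break — a
  hit.  The stop then sits inside the matched envelope where the locus caller
  reads it as pseudogene evidence.  Penalizing stops in inserts too keeps the
  aligner from silently threading through stop-riddled intervening sequence
  (an inserted intron, say) at no cost.
* ``'X'`` (codons containing N) emits at 0 bits everywhere: assembly gaps are
  score-neutral and can never create or destroy evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .sixframe import FramePeptide, map_peptide_to_genome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

STOP_LOG_ODDS = -20.0  # bits emitted for '*' by every match state
NEG = -np.inf

__all__ = [
    "AMINO_ACIDS",
    "HomeodomainAlignment",
    "ProfileHMM",
    "DomainHit",
    "ViterbiHit",
    "build_profile",
    "viterbi_score",
    "scan",
]


@dataclass
class HomeodomainAlignment:
    """An aligned amino-acid set: equal-length rows over 20 residues plus '-'."""

    rows: list[str]
    labels: list[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        width = len(self.rows[0])
        allowed = set(AMINO_ACIDS + "-")
        for label, row in zip(self.labels, self.rows):
            if len(row) != width:
                raise ValueError(f"row {label!r} has length {len(row)}, expected {width}")
            bad = set(row) - allowed
            if bad:
                raise ValueError(f"row {label!r} has invalid characters {sorted(bad)!r}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    @classmethod
    def from_fasta(cls, path) -> "HomeodomainAlignment":
        records = list(SeqIO.parse(path, "fasta"))
        return cls(
            rows=[str(r.seq).upper() for r in records],
            labels=[r.id for r in records],
        )


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with log2-odds emissions.

    Transition arrays are indexed by *from position* ``j`` (0..M-1, where
    position 0 is the begin state treated as match state 0):
    ``t_mm[j]`` = M_j->M_{j+1}, ``t_mi[j]`` = M_j->I_j, ``t_md[j]`` =
    M_j->D_{j+1}, ``t_ii``/``t_im`` from I_j, ``t_dd``/``t_dm`` from D_j
    (entries at j<1 are unused placeholders).  All transition values are log2
    probabilities; insert emissions are fixed at background (0 bits).  Local
    entry into any match state costs ``-log2(M)`` (uniform entry, folded into
    the score); exit is free.
    """

    M: int
    background: np.ndarray  # (20,) probabilities
    match_log_odds: np.ndarray  # (M, 20) log2-odds vs background
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_ii: np.ndarray
    t_im: np.ndarray
    t_dd: np.ndarray
    t_dm: np.ndarray
    match_columns: list[int] = field(default_factory=list)  # source alignment columns

    @property
    def entry_log2(self) -> float:
        return -float(np.log2(self.M))

    def consensus(self) -> str:
        """Per-state argmax residues — the model's highest-scoring peptide."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_log_odds, axis=1))

    def emission_scores(self, peptide: str) -> np.ndarray:
        """(len(peptide), M) matrix of per-state emission log-odds, in bits."""
        n = len(peptide)
        out = np.empty((n, self.M))
        for i, ch in enumerate(peptide):
            if ch in _AA_INDEX:
                out[i] = self.match_log_odds[:, _AA_INDEX[ch]]
            elif ch == "*":
                out[i] = STOP_LOG_ODDS
            elif ch == "X":
                out[i] = 0.0
            else:
                raise ValueError(f"invalid peptide character {ch!r}")
        return out

    def insert_scores(self, peptide: str) -> np.ndarray:
        """Per-residue insert-state emission log-odds: background (0) except stops."""
        return np.array([STOP_LOG_ODDS if ch == "*" else 0.0 for ch in peptide])

    # -- persistence ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "M": self.M,
            "background": self.background.tolist(),
            "match_log_odds": self.match_log_odds.tolist(),
            "match_columns": self.match_columns,
            **{
                k: getattr(self, k).tolist()
                for k in ("t_mm", "t_mi", "t_md", "t_ii", "t_im", "t_dd", "t_dm")
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            M=payload["M"],
            background=np.asarray(payload["background"]),
            match_log_odds=np.asarray(payload["match_log_odds"]),
            match_columns=list(payload["match_columns"]),
            **{
                k: np.asarray(payload[k])
                for k in ("t_mm", "t_mi", "t_md", "t_ii", "t_im", "t_dd", "t_dm")
            },
        )


def build_profile(
    alignment: HomeodomainAlignment,
    match_occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment, hmmbuild-style.

    Columns whose non-gap occupancy is >= the threshold become match states,
    in order.  Match emissions are column frequencies smoothed with
    background-proportional pseudocounts (total pseudo-mass ``20 *
    pseudocount`` distributed as the background), expressed as log2 odds
    against the background (pooled residue frequencies over the whole
    alignment, +1 smoothed, so no residue has zero probability).  Transitions
    are counted from each row's path through the match/insert/delete
    architecture with flat pseudocounts.
    """
    if not (0.0 < match_occupancy_threshold <= 1.0):
        raise ValueError("match_occupancy_threshold must be in (0, 1]")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    n_rows = len(alignment.rows)
    width = alignment.n_columns
    if width == 0:
        raise ValueError("empty alignment")

    match_cols = [
        c
        for c in range(width)
        if sum(1 for row in alignment.rows if row[c] != "-") / n_rows
        >= match_occupancy_threshold
    ]
    M = len(match_cols)
    if M < 1:
        raise ValueError("no column reaches the match occupancy threshold")
    is_match = [False] * width
    for c in match_cols:
        is_match[c] = True

    # background: pooled residue frequencies, +1 smoothing
    bg_counts = np.ones(20)
    for row in alignment.rows:
        for ch in row:
            if ch != "-":
                bg_counts[_AA_INDEX[ch]] += 1
    background = bg_counts / bg_counts.sum()

    # match emissions with background-proportional pseudocounts (hmmbuild
    # semantics): a residue never observed in the column scores below
    # background, instead of inheriting a flat-Laplace bonus over rare
    # background residues
    match_log_odds = np.empty((M, 20))
    for s, c in enumerate(match_cols):
        counts = np.zeros(20)
        for row in alignment.rows:
            if row[c] != "-":
                counts[_AA_INDEX[row[c]]] += 1
        probs = (counts + 20 * pseudocount * background) / (
            counts.sum() + 20 * pseudocount
        )
        match_log_odds[s] = np.log2(probs / background)

    # transitions: count each row's state path; positions j = 0..M-1
    cnt = {k: np.zeros(M) for k in ("mm", "mi", "md", "ii", "im", "dd", "dm")}
    for row in alignment.rows:
        path: list[tuple[str, int]] = [("M", 0)]  # begin acts as M_0
        j = 0
        for c in range(width):
            if is_match[c]:
                j += 1
                path.append(("M" if row[c] != "-" else "D", j))
            elif row[c] != "-":
                path.append(("I", j))
        for (s1, j1), (s2, j2) in zip(path, path[1:]):
            key = (s1 + s2).lower()
            # D->I and I->D are outside the architecture; skip them
            if key in cnt and j1 < M:
                cnt[key][j1] += 1

    pc = pseudocount
    with np.errstate(divide="ignore"):
        m_tot = cnt["mm"] + cnt["mi"] + cnt["md"] + 3 * pc
        i_tot = cnt["ii"] + cnt["im"] + 2 * pc
        d_tot = cnt["dd"] + cnt["dm"] + 2 * pc
        t_mm = np.log2((cnt["mm"] + pc) / m_tot)
        t_mi = np.log2((cnt["mi"] + pc) / m_tot)
        t_md = np.log2((cnt["md"] + pc) / m_tot)
        t_ii = np.log2((cnt["ii"] + pc) / i_tot)
        t_im = np.log2((cnt["im"] + pc) / i_tot)
        t_dd = np.log2((cnt["dd"] + pc) / d_tot)
        t_dm = np.log2((cnt["dm"] + pc) / d_tot)

    return ProfileHMM(
        M=M,
        background=background,
        match_log_odds=match_log_odds,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_ii=t_ii,
        t_im=t_im,
        t_dd=t_dd,
        t_dm=t_dm,
        match_columns=match_cols,
    )


@dataclass(frozen=True)
class ViterbiHit:
    """Best local alignment: score in bits, residue envelope, match-state span.

    ``envelope`` is 0-based half-open on the peptide; ``state_span`` is
    1-based inclusive over match states.  ``matched_peptide`` holds only the
    residues emitted by match states (insert-state residues dropped, deleted
    states omitted) — the cleanest homeodomain reconstruction for downstream
    identity comparisons.
    """

    bit_score: float
    envelope: tuple[int, int]
    state_span: tuple[int, int]
    matched_peptide: str = ""


def viterbi_score(hmm: ProfileHMM, peptide: str) -> ViterbiHit:
    """Maximum-scoring local alignment of ``peptide`` against the profile.

    Local in both sequence and model: the path enters directly into any match
    state (uniform entry cost ``-log2(M)``), may pass through insert and
    delete states, and exits freely from any match state.  Deterministic:
    among equal-scoring alignments the one ending earliest is reported, and
    traceback prefers longer continuations over fresh entries.
    """
    if len(peptide) == 0:
        raise ValueError("empty peptide")
    n, M = len(peptide), hmm.M
    S = hmm.emission_scores(peptide)
    SI = hmm.insert_scores(peptide)
    entry = hmm.entry_log2

    # DP matrices over (residue i in 1..n, state j in 1..M); index 0 = boundary
    VM = np.full((n + 1, M + 1), NEG)
    VI = np.full((n + 1, M + 1), NEG)
    VD = np.full((n + 1, M + 1), NEG)

    # delete-chain prefix sums: chaining D_m..D_j costs P[j] - P[m]
    # P indexed by j = 2..M; t_dd[k] is D_k -> D_{k+1}
    if M >= 2:
        P = np.concatenate([[0.0], np.cumsum(hmm.t_dd[2:M])])  # aligned to j=2..M

    for i in range(1, n + 1):
        prevM, prevI, prevD = VM[i - 1], VI[i - 1], VD[i - 1]
        cand = np.full(M, entry)
        np.maximum(cand, prevM[:-1] + hmm.t_mm, out=cand)
        np.maximum(cand, prevI[:-1] + hmm.t_im, out=cand)
        np.maximum(cand, prevD[:-1] + hmm.t_dm, out=cand)
        VM[i, 1:] = S[i - 1] + cand
        # inserts I_j for j = 1..M-1 (flanking inserts are outside the envelope)
        if M >= 2:
            VI[i, 1:M] = SI[i - 1] + np.maximum(
                VM[i - 1, 1:M] + hmm.t_mi[1:M], prevI[1:M] + hmm.t_ii[1:M]
            )
            # deletes D_j, j >= 2, entered from M_{j-1}; solved along the row by
            # a running max over the delete chain
            f = VM[i, 1:M] + hmm.t_md[1:M]  # entry into D_j via M_{j-1}, j=2..M
            g = np.maximum.accumulate(f - P)
            VD[i, 2:] = P + g

    flat = int(np.argmax(VM))
    best_i, best_j = divmod(flat, M + 1)
    best = float(VM[best_i, best_j])

    # traceback (recomputation with tolerance); prefers continuation over entry
    tol = 1e-9
    i, j, state = best_i, best_j, "M"
    end_i, end_j = best_i, best_j
    matched: list[tuple[int, str]] = []
    while True:
        if state == "M":
            matched.append((j, peptide[i - 1]))
            target = VM[i, j] - S[i - 1, j - 1]
            if j >= 2 and abs(VM[i - 1, j - 1] + hmm.t_mm[j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "M"
            elif j >= 2 and abs(VI[i - 1, j - 1] + hmm.t_im[j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "I"
            elif j >= 2 and abs(VD[i - 1, j - 1] + hmm.t_dm[j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "D"
            else:  # fresh entry
                break
        elif state == "I":
            if abs(VM[i - 1, j] + hmm.t_mi[j] + SI[i - 1] - VI[i, j]) < tol:
                i, state = i - 1, "M"
            else:
                i = i - 1
        else:  # D
            if abs(VM[i, j - 1] + hmm.t_md[j - 1] - VD[i, j]) < tol:
                j, state = j - 1, "M"
            else:
                j = j - 1

    start_i, start_j = i, j
    return ViterbiHit(
        bit_score=best,
        envelope=(start_i - 1, end_i),
        state_span=(start_j, end_j),
        matched_peptide="".join(ch for _, ch in reversed(matched)),
    )


@dataclass(frozen=True)
class DomainHit:
    """A reported homeodomain match on one frame peptide, with genomic placement."""

    sequence_id: str
    frame: int
    peptide_start: int
    peptide_end: int
    genomic_start: int
    genomic_end: int
    strand: str
    bit_score: float
    state_start: int
    state_end: int
    peptide: str
    genome: str | None = None
    rescued: bool = False
    matched_peptide: str = ""  # residues emitted by match states only

    @property
    def n_states(self) -> int:
        return self.state_end - self.state_start + 1


def scan(
    hmm: ProfileHMM,
    frames: list[FramePeptide],
    bit_threshold: float = 15.0,
    min_envelope: int = 12,
    genome: str | None = None,
    rescue: bool = True,
    rescue_threshold: float = 3.0,
) -> list[DomainHit]:
    """All non-overlapping local hits scoring >= ``bit_threshold``.

    Found greedily per frame peptide: take the best hit, mask its envelope,
    and rescan the flanking segments until nothing reaches the threshold.
    Envelopes shorter than ``min_envelope`` residues are suppressed (but still
    masked, so they cannot shadow neighbouring hits).  Genomic coordinates
    come from :func:`homeodyn.sixframe.map_peptide_to_genome`.

    With ``rescue`` on (the default), every hit that stops short of the
    model's ends triggers a *fragment rescue*: the few codons immediately
    beyond the hit are searched in the other same-strand frames at the
    permissive ``rescue_threshold``, accepting only fragments whose match
    states continue where the primary hit left off.  This recovers the small
    far-side fragment of a frameshifted homeobox — a helix-3 frameshift
    leaves a tail of just a dozen residues, far below the reporting threshold
    on its own — while the continuity constraint keeps background noise out.
    Rescued hits are flagged ``rescued=True``.
    """
    if not np.isfinite(bit_threshold):
        raise ValueError("bit_threshold must be finite")
    hits: list[DomainHit] = []
    for fp in frames:
        _scan_segment(hmm, fp, fp.peptide, 0, bit_threshold, min_envelope, genome, hits)
    if rescue:
        _rescue_fragments(hmm, frames, hits, rescue_threshold, genome)
    hits.sort(key=lambda h: (h.sequence_id, h.genomic_start, h.genomic_end, h.frame))
    return hits


def _rescue_fragments(
    hmm: ProfileHMM,
    frames: list[FramePeptide],
    hits: list[DomainHit],
    rescue_threshold: float,
    genome: str | None,
) -> None:
    by_key = {(fp.sequence_id, fp.frame): fp for fp in frames}
    M = hmm.M
    for hit in list(hits):
        if hit.rescued:
            continue
        sides = []
        if hit.state_end <= M - 3:
            sides.append("down")
        if hit.state_start >= 4:
            sides.append("up")
        for side in sides:
            if _has_adjacent_continuation(hit, side, hits):
                continue
            if side == "down":
                need = 3 * (M - hit.state_end) + 18
                if hit.strand == "+":
                    window = (hit.genomic_end - 6, hit.genomic_end + need)
                else:
                    window = (hit.genomic_start - need, hit.genomic_start + 6)
            else:
                need = 3 * (hit.state_start - 1) + 18
                if hit.strand == "+":
                    window = (hit.genomic_start - need, hit.genomic_start + 6)
                else:
                    window = (hit.genomic_end - 6, hit.genomic_end + need)
            for (seq_id, frame), fp in by_key.items():
                if seq_id != hit.sequence_id:
                    continue
                if (frame > 0) != (hit.strand == "+"):
                    continue
                win = window
                if frame == hit.frame:
                    # same-frame fragment (e.g. clipped by a stop codon): keep
                    # the window clear of the anchor's own envelope
                    grows_right = (side == "down") == (hit.strand == "+")
                    if grows_right:
                        win = (hit.genomic_end, window[1])
                    else:
                        win = (window[0], hit.genomic_start)
                frag = _rescue_in_frame(
                    hmm, fp, win, hit, side, rescue_threshold, genome
                )
                if frag is not None and not any(
                    h.frame == frag.frame
                    and h.sequence_id == frag.sequence_id
                    and h.genomic_start < frag.genomic_end
                    and frag.genomic_start < h.genomic_end
                    for h in hits
                ):
                    hits.append(frag)


def _has_adjacent_continuation(
    hit: DomainHit, side: str, hits: list[DomainHit], adjacency: int = 300
) -> bool:
    """True if another nearby hit already provides the missing match states."""
    for h in hits:
        if h is hit or h.sequence_id != hit.sequence_id or h.strand != hit.strand:
            continue
        gap = max(h.genomic_start, hit.genomic_start) - min(
            h.genomic_end, hit.genomic_end
        )
        if gap > adjacency:
            continue
        if side == "down" and h.state_end > hit.state_end:
            return True
        if side == "up" and h.state_start < hit.state_start:
            return True
    return False


def _rescue_in_frame(
    hmm: ProfileHMM,
    fp: FramePeptide,
    window: tuple[int, int],
    anchor: DomainHit,
    side: str,
    rescue_threshold: float,
    genome: str | None,
) -> DomainHit | None:
    off = fp.offset
    L = fp.source_length
    n_res = len(fp.peptide)
    wstart, wend = max(0, window[0]), min(L, window[1])
    if wend <= wstart:
        return None
    if fp.frame > 0:
        r0 = max(0, (wstart - off) // 3)
        r1 = min(n_res, -(-(wend - off) // 3))
    else:
        r0 = max(0, (L - off - wend) // 3)
        r1 = min(n_res, -(-(L - off - wstart) // 3))
    if r1 - r0 < 4:
        return None
    vh = viterbi_score(hmm, fp.peptide[r0:r1])
    if vh.bit_score < rescue_threshold:
        return None
    s, e = vh.envelope
    if e - s < 4:
        return None
    # the fragment's match states must continue where the anchor stopped,
    # and must add coverage the anchor does not already have
    if side == "down" and (
        vh.state_span[0] < anchor.state_end - 2 or vh.state_span[1] <= anchor.state_end
    ):
        return None
    if side == "up" and (
        vh.state_span[1] > anchor.state_start + 2
        or vh.state_span[0] >= anchor.state_start
    ):
        return None
    (gstart, gend), strand = map_peptide_to_genome(L, fp.frame, (r0 + s, r0 + e))
    return DomainHit(
        sequence_id=fp.sequence_id,
        frame=fp.frame,
        peptide_start=r0 + s,
        peptide_end=r0 + e,
        genomic_start=gstart,
        genomic_end=gend,
        strand=strand,
        bit_score=vh.bit_score,
        state_start=vh.state_span[0],
        state_end=vh.state_span[1],
        peptide=fp.peptide[r0 + s : r0 + e],
        genome=genome,
        rescued=True,
        matched_peptide=vh.matched_peptide,
    )


def _scan_segment(
    hmm: ProfileHMM,
    fp: FramePeptide,
    segment: str,
    offset: int,
    bit_threshold: float,
    min_envelope: int,
    genome: str | None,
    hits: list[DomainHit],
) -> None:
    if len(segment) == 0:
        return
    vh = viterbi_score(hmm, segment)
    if vh.bit_score < bit_threshold:
        return
    s, e = vh.envelope
    if e - s >= min_envelope:
        (gstart, gend), strand = map_peptide_to_genome(
            fp.source_length, fp.frame, (offset + s, offset + e)
        )
        hits.append(
            DomainHit(
                sequence_id=fp.sequence_id,
                frame=fp.frame,
                peptide_start=offset + s,
                peptide_end=offset + e,
                genomic_start=gstart,
                genomic_end=gend,
                strand=strand,
                bit_score=vh.bit_score,
                state_start=vh.state_span[0],
                state_end=vh.state_span[1],
                peptide=segment[s:e],
                genome=genome,
                matched_peptide=vh.matched_peptide,
            )
        )
    _scan_segment(hmm, fp, segment[:s], offset, bit_threshold, min_envelope, genome, hits)
    _scan_segment(
        hmm, fp, segment[e:], offset + e, bit_threshold, min_envelope, genome, hits
    )


def write_hits_tsv(hits: list[DomainHit], path) -> None:
    """Tab-separated hit table; genomic coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "sequence_id\tframe\tpeptide_start\tpeptide_end\tgenomic_start\t"
            "genomic_end\tstrand\tbit_score\tstate_start\tstate_end\tpeptide\n"
        )
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.frame}\t{h.peptide_start}\t{h.peptide_end}\t"
                f"{h.genomic_start + 1}\t{h.genomic_end}\t{h.strand}\t"
                f"{h.bit_score:.3f}\t{h.state_start}\t{h.state_end}\t{h.peptide}\n"
            )


def read_hits_tsv(path, genome: str | None = None) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence_id"):
            raise ValueError("not a homeodyn hits table")
        for line in fh:
            (
                seq_id,
                frame,
                ps,
                pe,
                gs,
                ge,
                strand,
                score,
                ss,
                se,
                pep,
            ) = line.rstrip("\n").split("\t")
            hits.append(
                DomainHit(
                    sequence_id=seq_id,
                    frame=int(frame),
                    peptide_start=int(ps),
                    peptide_end=int(pe),
                    genomic_start=int(gs) - 1,
                    genomic_end=int(ge),
                    strand=strand,
                    bit_score=float(score),
                    state_start=int(ss),
                    state_end=int(se),
                    peptide=pep,
                    genome=genome,
                )
            )
    return hits
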
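"""Profile hidden Markov model scanning of protein sequences.

The scorer implements Plan-7-style *local* alignment of a protein against a
profile HMM.  A single hit is a path that enters the profile at any match
column ``k`` (uniform entry probability ``1/L``), walks match/insert/delete
states column by column, and exits from any match column ``l`` (uniform exit
``1/L``).  The bit score is the log2-odds of the hit path(s) against the null
model over the emitted subsequence::

    bitscore = log2( P(path(s), subsequence | profile) / P(subsequence | null) )

``viterbi`` scores the single best path; ``forward`` sums over all single-hit
paths (and is therefore never smaller).  Flanking residues outside the hit
envelope are emitted by the null model under both hypotheses and cancel from
the odds ratio, so only the envelope is scored.

Residues outside the 20-letter alphabet (``X`` and friends) are emitted by
the null distribution in every state, i.e. they contribute zero bits.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .records import AMINO_ACIDS, BgcmineError, DomainHit, Gene, GAP

# transition order within a profile column, matching the file format
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: default gathering cutoff when a profile file carries none
DEFAULT_CUTOFF_BITS = 20.0

#: hits below this many bits are not reported at all
REPORT_FLOOR_BITS = 0.0


class ProfileParseError(BgcmineError):
    """Raised for malformed profile files; carries the offending line number."""


@dataclass
class ProfileModel:
    """A profile HMM over the 20 amino acids.

    All emission/transition tables hold probabilities (not log space).
    ``transitions[c]`` holds the seven probabilities for moves out of column
    ``c`` in the order M->M, M->I, M->D, I->M, I->I, D->M, D->D.
    """

    name: str
    length: int
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L, 20)
    transitions: np.ndarray  # (L, 7)
    null_model: np.ndarray  # (20,)
    cutoff_bits: float = DEFAULT_CUTOFF_BITS
    _logodds: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.insert_emissions = np.asarray(self.insert_emissions, float)
        self.transitions = np.asarray(self.transitions, float)
        self.null_model = np.asarray(self.null_model, float)
        if self.length < 1:
            raise ValueError(f"profile {self.name}: length must be >= 1")
        if self.match_emissions.shape != (self.length, 20):
            raise ValueError(f"profile {self.name}: bad match emission shape")
        if not math.isfinite(self.cutoff_bits):
            raise ValueError(f"profile {self.name}: cutoff must be finite")
        for row in self.match_emissions:
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile {self.name}: match row not normalized")
        for row in self.insert_emissions:
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile {self.name}: insert row not normalized")
        if abs(self.null_model.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile {self.name}: null model not normalized")

    @property
    def consensus(self) -> str:
        """Highest-emission residue of each match column."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    def logodds(self):
        """Cached log2-odds tables (match, insert, transitions, entry/exit)."""
        if self._logodds is None:
            with np.errstate(divide="ignore"):
                lnull = np.log2(self.null_model)
                m = np.log2(self.match_emissions) - lnull
                ins = np.log2(self.insert_emissions) - lnull
                t = np.log2(self.transitions)
            # unknown residue (index -1): zero bits in every state
            m = np.hstack([m, np.zeros((self.length, 1))])
            ins = np.hstack([ins, np.zeros((self.length, 1))])
            entry = -math.log2(self.length)
            self._logodds = (m, ins, t, entry)
        return self._logodds


def encode_protein(translation: str) -> np.ndarray:
    """Map residues to alphabet indices; anything non-standard becomes -1."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in translation.upper()],
                    dtype=np.int64)


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

_NEG = -np.inf
# traceback codes
_P_ENTRY, _P_M, _P_I, _P_D = 0, 1, 2, 3


def _viterbi_dp(x: np.ndarray, profile: ProfileModel):
    """Viterbi matrices + pointers for sequence indices ``x``.

    Returns (VM, ptrM, ptrI, ptrD, exit_bonus); VM[j, c] is the best
    log2-odds of a path ending in match column c at residue j.
    """
    L = profile.length
    n = len(x)
    m_lo, i_lo, t_lo, entry = profile.logodds()
    VM = np.full((n, L), _NEG)
    VI = np.full((n, L), _NEG)
    VD = np.full((n, L), _NEG)
    ptrM = np.zeros((n, L), dtype=np.int8)
    ptrI = np.zeros((n, L), dtype=np.int8)
    ptrD = np.zeros((n, L), dtype=np.int8)

    tMM, tMI, tMD = t_lo[:, T_MM], t_lo[:, T_MI], t_lo[:, T_MD]
    tIM, tII = t_lo[:, T_IM], t_lo[:, T_II]
    tDM, tDD = t_lo[:, T_DM], t_lo[:, T_DD]

    for j in range(n):
        em = m_lo[:, x[j]]
        if j == 0:
            VM[j] = em + entry
            ptrM[j] = _P_ENTRY
        else:
            prevM = VM[j - 1]
            prevI = VI[j - 1]
            prevD = VD[j - 1]
            # shifted by one column: transitions from column c-1 into c
            fm = np.concatenate(([_NEG], prevM[:-1] + tMM[:-1]))
            fi = np.concatenate(([_NEG], prevI[:-1] + tIM[:-1]))
            fd = np.concatenate(([_NEG], prevD[:-1] + tDM[:-1]))
            fe = np.full(L, entry)
            stack = np.stack([fe, fm, fi, fd])
            ptrM[j] = stack.argmax(axis=0)
            VM[j] = em + stack.max(axis=0)
            # inserts stay in the same column
            im = prevM + tMI
            ii = prevI + tII
            take_i = ii > im
            ptrI[j] = np.where(take_i, _P_I, _P_M)
            VI[j] = i_lo[:, x[j]] + np.where(take_i, ii, im)
        # deletes within the same row, sequential over columns
        for c in range(1, L):
            dm = VM[j, c - 1] + tMD[c - 1]
            dd = VD[j, c - 1] + tDD[c - 1]
            if dd > dm:
                VD[j, c] = dd
                ptrD[j, c] = _P_D
            else:
                VD[j, c] = dm
                ptrD[j, c] = _P_M
    return VM, ptrM, ptrI, ptrD, entry


def viterbi_score(translation: str, profile: ProfileModel) -> float:
    """Best single-hit log2-odds score (bits); -inf for an empty sequence."""
    x = encode_protein(translation)
    if len(x) == 0:
        return _NEG
    VM, *_rest, exit_bonus = _viterbi_dp(x, profile)
    return float(VM.max() + exit_bonus)


def forward_score(translation: str, profile: ProfileModel) -> float:
    """Log2 of the summed odds over *all* single-hit paths (bits)."""
    x = encode_protein(translation)
    n = len(x)
    if n == 0:
        return _NEG
    L = profile.length
    m_lo, i_lo, t_lo, entry = profile.logodds()
    tMM, tMI, tMD = t_lo[:, T_MM], t_lo[:, T_MI], t_lo[:, T_MD]
    tIM, tII = t_lo[:, T_IM], t_lo[:, T_II]
    tDM, tDD = t_lo[:, T_DM], t_lo[:, T_DD]
    FM = np.full((n, L), _NEG)
    FI = np.full((n, L), _NEG)
    FD = np.full((n, L), _NEG)
    for j in range(n):
        em = m_lo[:, x[j]]
        if j == 0:
            FM[j] = em + entry
        else:
            fm = np.concatenate(([_NEG], FM[j - 1][:-1] + tMM[:-1]))
            fi = np.concatenate(([_NEG], FI[j - 1][:-1] + tIM[:-1]))
            fd = np.concatenate(([_NEG], FD[j - 1][:-1] + tDM[:-1]))
            acc = np.logaddexp2(np.logaddexp2(fm, fi), np.logaddexp2(fd, entry))
            FM[j] = em + acc
            FI[j] = i_lo[:, x[j]] + np.logaddexp2(FM[j - 1] + tMI, FI[j - 1] + tII)
        for c in range(1, L):
            FD[j, c] = np.logaddexp2(FM[j, c - 1] + tMD[c - 1],
                                     FD[j, c - 1] + tDD[c - 1])
    return float(np.logaddexp2.reduce((FM + entry).ravel()))


def _traceback(x, profile, VM, ptrM, ptrI, ptrD, j, c):
    """Recover envelope and consensus-column -> residue map from (j, c)."""
    alignment: dict[int, Optional[int]] = {}
    state = _P_M
    while True:
        if state == _P_M:
            alignment[c + 1] = int(j)
            move = ptrM[j, c]
            if move == _P_ENTRY:
                return int(j), alignment
            if move == _P_M:
                j, c, state = j - 1, c - 1, _P_M
            elif move == _P_I:
                j, c, state = j - 1, c - 1, _P_I
            else:
                j, c, state = j - 1, c - 1, _P_D
        elif state == _P_I:
            # insert residues are not part of the consensus map
            move = ptrI[j, c]
            state = _P_M if move == _P_M else _P_I
            j = j - 1
        else:  # delete: consumes a column, no residue
            alignment[c + 1] = GAP
            move = ptrD[j, c]
            state = _P_M if move == _P_M else _P_D
            c = c - 1


def scan_protein(
    translation: str,
    profile: ProfileModel,
    mode: str = "viterbi",
    gene_id: str = "",
    floor_bits: float = REPORT_FLOOR_BITS,
) -> list[DomainHit]:
    """Find all non-overlapping hits of ``profile`` on a protein.

    Hits are located greedily: the best-scoring Viterbi hit is reported, its
    envelope is excised, and the flanking segments are re-scanned until no
    segment scores ``floor_bits`` or better.  With ``mode="forward"`` each
    hit keeps its Viterbi envelope and alignment but is re-scored with the
    forward algorithm over its segment.
    """
    if mode not in ("viterbi", "forward"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if len(translation) < 1:
        raise ValueError("empty translation")
    x_full = encode_protein(translation)
    hits: list[DomainHit] = []
    segments = [(0, len(x_full))]
    while segments:
        lo, hi = segments.pop()
        if hi - lo < 1:
            continue
        x = x_full[lo:hi]
        VM, ptrM, ptrI, ptrD, exit_bonus = _viterbi_dp(x, profile)
        flat = int(VM.argmax())
        j, c = divmod(flat, profile.length)
        score = float(VM[j, c] + exit_bonus)
        if not math.isfinite(score) or score < floor_bits:
            continue
        env_start, alignment = _traceback(x, profile, VM, ptrM, ptrI, ptrD, j, c)
        env_end = j + 1
        if mode == "forward":
            score = forward_score(translation[lo:hi], profile)
        hits.append(
            DomainHit(
                gene_id=gene_id,
                profile=profile.name,
                env_start=lo + env_start,
                env_end=lo + env_end,
                bitscore=score,
                alignment={col: (None if r is GAP else lo + r)
                           for col, r in alignment.items()},
            )
        )
        segments.append((lo, lo + env_start))
        segments.append((lo + env_end, hi))
    hits.sort(key=lambda h: (h.env_start, h.env_end))
    return hits


def scan_genes(
    genes: Iterable[Gene],
    profiles: Iterable[ProfileModel],
    mode: str = "viterbi",
) -> list[DomainHit]:
    """Scan every gene against every profile; hits are unfiltered."""
    profiles = list(profiles)
    out: list[DomainHit] = []
    for gene in genes:
        for profile in profiles:
            out.extend(scan_protein(gene.translation, profile, mode=mode,
                                    gene_id=gene.gene_id))
    return out


# ---------------------------------------------------------------------------
# hit filtering and family assignment
# ---------------------------------------------------------------------------

def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    inter = min(a.env_end, b.env_end) - max(a.env_start, b.env_start)
    if inter <= 0:
        return 0.0
    shorter = min(a.env_end - a.env_start, b.env_end - b.env_start)
    return inter / shorter


def filter_hits(
    hits: Sequence[DomainHit],
    profiles: Union[dict, Sequence[ProfileModel]],
    max_overlap: float = 0.5,
) -> list[DomainHit]:
    """Apply per-profile bit cutoffs and resolve same-profile overlaps.

    Hits below their profile's gathering cutoff are dropped.  Among hits of
    the same profile on the same gene overlapping by more than
    ``max_overlap`` of the shorter envelope, the best score wins (ties go to
    the smaller ``env_start``).  Idempotent.
    """
    by_name = (profiles if isinstance(profiles, dict)
               else {p.name: p for p in profiles})
    passing = [h for h in hits
               if h.profile in by_name
               and h.bitscore >= by_name[h.profile].cutoff_bits]
    kept: list[DomainHit] = []
    groups: dict[tuple, list[DomainHit]] = {}
    for h in passing:
        groups.setdefault((h.gene_id, h.profile), []).append(h)
    for key in sorted(groups):
        group = sorted(groups[key],
                       key=lambda h: (-h.bitscore, h.env_start, h.env_end))
        chosen: list[DomainHit] = []
        for h in group:
            if all(_overlap_fraction(h, k) <= max_overlap for k in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.gene_id, h.env_start, h.env_end, h.profile))
    return kept


def assign_family(
    gene: Union[Gene, str],
    family_profiles: Iterable[ProfileModel],
) -> Optional[tuple[str, float]]:
    """smCOG-style call: best-scoring family profile above its cutoff.

    Returns ``(family_name, bitscore)`` or ``None`` when nothing passes.
    Ties are broken toward the lexicographically smaller name.
    """
    translation = gene.translation if isinstance(gene, Gene) else gene
    best: Optional[tuple[str, float]] = None
    for profile in family_profiles:
        score = viterbi_score(translation, profile)
        if score < profile.cutoff_bits:
            continue
        if (best is None or score > best[1]
                or (score == best[1] and profile.name < best[0])):
            best = (profile.name, score)
    return best


# ---------------------------------------------------------------------------
# profile file I/O (documented HMMER3 text subset)
# ---------------------------------------------------------------------------

def _neglog_fields(line: str, expected: int, lineno: int) -> list[float]:
    fields = line.split()
    if len(fields) != expected:
        raise ProfileParseError(
            f"line {lineno}: expected {expected} values, got {len(fields)}"
        )
    out = []
    for f in fields:
        if f == "*":
            out.append(0.0)  # -ln p = infinity  =>  p = 0
        else:
            out.append(math.exp(-float(f)))
    return out


def load_profiles(path) -> list[ProfileModel]:
    """Read profiles from the documented HMMER3-flavoured text subset.

    Emission and transition values are stored as negative natural-log
    probabilities; ``*`` denotes probability zero.  Recognized per-profile
    header lines: ``NAME``, ``LENG``, ``ALPH``, ``CUTOFF GA <bits>``,
    ``NULL`` (20 values).  Each match column contributes three lines:
    20 match emissions, 20 insert emissions, 7 transitions.
    """
    profiles: list[ProfileModel] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("HMMER3"):
            i += 1
            continue
        # start of a profile stanza
        name = None
        length = None
        cutoff = DEFAULT_CUTOFF_BITS
        null = np.full(20, 1 / 20)
        while i < n:
            stripped = lines[i].strip()
            if stripped.startswith("NAME"):
                name = stripped.split(None, 1)[1].strip()
            elif stripped.startswith("LENG"):
                length = int(stripped.split()[1])
            elif stripped.startswith("CUTOFF"):
                cutoff = float(stripped.split()[2])
            elif stripped.startswith("GA "):
                cutoff = float(stripped.split()[1].rstrip(";"))
            elif stripped.startswith("NULL"):
                null = np.array(
                    _neglog_fields(stripped[4:], 20, i + 1))
            elif stripped.startswith("HMM"):
                i += 1  # skip transition header line that follows
                break
            i += 1
        else:
            raise ProfileParseError(f"line {n}: truncated profile stanza")
        if name is None:
            raise ProfileParseError(f"line {i + 1}: profile missing NAME")
        if length is None:
            raise ProfileParseError(
                f"line {i + 1}: profile {name} missing LENG")
        i += 1
        match = np.empty((length, 20))
        insert = np.empty((length, 20))
        trans = np.empty((length, 7))
        for c in range(length):
            if i + 2 >= n:
                raise ProfileParseError(
                    f"line {n}: profile {name} truncated at column {c + 1}")
            mfields = lines[i].split()
            if not mfields or mfields[0] != str(c + 1):
                raise ProfileParseError(
                    f"line {i + 1}: expected match line for column {c + 1}")
            match[c] = _neglog_fields(" ".join(mfields[1:21]), 20, i + 1)
            insert[c] = _neglog_fields(lines[i + 1], 20, i + 2)
            trans[c] = _neglog_fields(lines[i + 2], 7, i + 3)
            i += 3
        while i < n and lines[i].strip() != "//":
            if lines[i].strip():
                raise ProfileParseError(
                    f"line {i + 1}: unexpected content before '//'")
            i += 1
        i += 1
        # renormalize tiny serialization round-off
        match /= match.sum(axis=1, keepdims=True)
        insert /= insert.sum(axis=1, keepdims=True)
        null = null / null.sum()
        profiles.append(ProfileModel(name, length, match, insert, trans,
                                     null, cutoff))
    if not profiles:
        raise ProfileParseError("line 1: no profiles in file")
    return profiles


def _fmt(p: float) -> str:
    if p <= 0:
        return "*"
    return f"{-math.log(p):.5f}"


def save_profiles(profiles: Iterable[ProfileModel], path) -> None:
    """Serialize profiles in the format read by :func:`load_profiles`."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write("HMMER3/f [bgcmine profile subset]\n")
            fh.write(f"NAME  {p.name}\n")
            fh.write(f"LENG  {p.length}\n")
            fh.write("ALPH  amino\n")
            fh.write(f"CUTOFF GA {p.cutoff_bits:.2f}\n")
            fh.write("NULL  " + " ".join(_fmt(v) for v in p.null_model) + "\n")
            fh.write("HMM   " + "  ".join(AMINO_ACIDS) + "\n")
            fh.write("      m->m m->i m->d i->m i->i d->m d->d\n")
            for c in range(p.length):
                fh.write(f"{c + 1:>7} " +
                         " ".join(_fmt(v) for v in p.match_emissions[c]) + "\n")
                fh.write("        " +
                         " ".join(_fmt(v) for v in p.insert_emissions[c]) + "\n")
                fh.write("        " +
                         " ".join(_fmt(v) for v in p.transitions[c]) + "\n")
            fh.write("//\n")


def save_profiles_hmmer(profiles: Iterable[ProfileModel], path) -> None:
    """Write profiles in full HMMER3/f layout accepted by ``hmmsearch``.

    Adds the node-0 block and STATS lines HMMER requires; the STATS
    calibration constants are placeholders adequate for score-thresholded
    searches (E-values from these files are not meaningful).
    """
    bg = np.full(20, 1 / 20)
    with open(path, "w") as fh:
        for p in profiles:
            fh.write("HMMER3/f [3.1b2 | February 2015]\n")
            fh.write(f"NAME  {p.name}\n")
            fh.write(f"LENG  {p.length}\n")
            fh.write("ALPH  amino\n")
            fh.write("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   no\n")
            fh.write("NSEQ  1\nEFFN  1.000000\nCKSUM 0\n")
            fh.write(f"GA    {p.cutoff_bits:.2f} {p.cutoff_bits:.2f};\n")
            fh.write("STATS LOCAL MSV      -9.0000  0.70000\n")
            fh.write("STATS LOCAL VITERBI  -9.5000  0.70000\n")
            fh.write("STATS LOCAL FORWARD  -4.0000  0.70000\n")
            fh.write("HMM          " +
                     "        ".join(AMINO_ACIDS) + "\n")
            fh.write("            m->m     m->i     m->d     i->m     i->i"
                     "     d->m     d->d\n")
            fh.write("  COMPO " +
                     " ".join(f"{-math.log(v):8.5f}" for v in p.null_model) + "\n")
            fh.write("        " +
                     " ".join(f"{-math.log(v):8.5f}" for v in bg) + "\n")
            t0 = p.transitions[0]
            fh.write("        " + " ".join(
                _fmt(v) if v > 0 else "*"
                for v in (t0[T_MM], t0[T_MI], t0[T_MD], 0.5, 0.5, 1.0, 0.0)
            ) + "\n")
            for c in range(p.length):
                cons = AMINO_ACIDS[int(p.match_emissions[c].argmax())]
                fh.write(f"{c + 1:>7} " +
                         " ".join(f"{-math.log(max(v, 1e-300)):8.5f}"
                                  for v in p.match_emissions[c]) +
                         f"      - {cons.lower()} - - -\n")
                fh.write("        " +
                         " ".join(f"{-math.log(max(v, 1e-300)):8.5f}"
                                  for v in p.insert_emissions[c]) + "\n")
                row = p.transitions[c]
                if c == p.length - 1:
                    vals = [row[T_MM], row[T_MI], None, 0.5, 0.5, 1.0, None]
                else:
                    vals = list(row)
                fh.write("        " + " ".join(
                    "       *" if (v is None or v <= 0) else f"{-math.log(v):8.5f}"
                    for v in vals) + "\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# external scanner adapter (HMMER hmmsearch)
# ---------------------------------------------------------------------------

class AdapterUnavailableError(BgcmineError):
    """The external scanner binary cannot be found."""


def parse_domtblout(path, genes: Optional[Iterable[Gene]] = None) -> list[DomainHit]:
    """Parse HMMER ``--domtblout`` output into :class:`DomainHit` objects.

    Envelope coordinates are converted from 1-based inclusive to 0-based
    half-open.  The table carries no per-column alignment, so the map is a
    linear pairing of the reported consensus span with the reported aligned
    span (an approximation adequate for window arithmetic, not for
    active-site extraction).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < 22:
                raise BgcmineError(
                    f"{path}: line {lineno}: not a domtblout row")
            target, query = f[0], f[3]
            score = float(f[13])
            hmm_from, hmm_to = int(f[15]), int(f[16])
            ali_from, ali_to = int(f[17]), int(f[18])
            env_from, env_to = int(f[19]), int(f[20])
            span = min(hmm_to - hmm_from, ali_to - ali_from)
            alignment = {hmm_from + k: ali_from - 1 + k for k in range(span + 1)}
            hits.append(DomainHit(
                gene_id=target,
                profile=query,
                env_start=env_from - 1,
                env_end=env_to,
                bitscore=score,
                alignment=alignment,
            ))
    return hits


def external_scanner_adapter(
    genes: Sequence[Gene],
    profile_db_path,
    binary: str = "hmmsearch",
) -> list[DomainHit]:
    """Run HMMER ``hmmsearch`` over the genes and parse its domain table.

    Results are interchangeable with :func:`scan_protein` output downstream
    (scores come from HMMER, not from the internal scorer).  A missing
    binary raises :class:`AdapterUnavailableError`; there is no fallback.
    """
    exe = shutil.which(binary)
    if exe is None:
        raise AdapterUnavailableError(
            f"external scanner adapter unavailable: {binary!r} not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = os.path.join(tmp, "genes.faa")
        table = os.path.join(tmp, "hits.domtblout")
        with open(fasta, "w") as fh:
            for g in genes:
                fh.write(f">{g.gene_id}\n{g.translation}\n")
        proc = subprocess.run(
            [exe, "--domtblout", table, "-T", "0", "--domT", "0",
             str(profile_db_path), fasta],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise BgcmineError(
                f"{binary} failed ({proc.returncode}): {proc.stderr.strip()}")
        return parse_domtblout(table, genes)
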
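"""Conserved noncoding elements and binding-site turnover.

A conserved noncoding element (CNE) is a reference interval at least
100 bp long where a minimum number of species (10+ avian, or 3+
non-avian tetrapods) align to the reference at better than 70% sequence
identity, excluding annotated exons. Identity is evaluated in sliding
100-bp reference-anchored windows with gaps counted as mismatches; a
reference base is conserved for a species when any covering window
clears the identity cutoff.

Binding-site turnover between reference and alternate alleles is scored
with Match-style position-weight-matrix similarity: an information-
weighted score normalized between the matrix's minimum and maximum
attainable values, with a separate score over the 5-position
highest-information core. A site is gained (lost) when a hit present in
one allele has no hit at the homologous offset and strand in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class AlignmentBlock:
    """Reference-anchored gapped alignment over a set of species."""

    ref_name: str
    ref_start: int  # 0-based reference coordinate of the first ref base
    ref_seq: str  # may contain gap columns for insertions in other species
    species_seqs: dict[str, str]
    clades: dict[str, str]  # species -> "avian" | "tetrapod"

    def __post_init__(self) -> None:
        n = len(self.ref_seq)
        for name, seq in self.species_seqs.items():
            if len(seq) != n:
                raise ValueError(f"{name}: aligned length {len(seq)} != {n}")
            if name not in self.clades:
                raise ValueError(f"{name} missing from the clade manifest")

    @property
    def ref_columns(self) -> np.ndarray:
        """Column indices carrying a reference base (non-gap)."""
        return np.flatnonzero(np.frombuffer(self.ref_seq.encode(), dtype=np.uint8) != ord("-"))

    def species_in_clade(self, clade: str) -> list[str]:
        return [s for s, c in self.clades.items() if c == clade]


@dataclass(frozen=True)
class CNEInterval:
    start: int  # 0-based half-open reference bp
    end: int
    clade: str
    supporting_species: int
    mean_identity: float


def _match_mask(block: AlignmentBlock, species: str) -> np.ndarray:
    """Per-reference-base match indicator (gap or mismatch = False)."""
    if species not in block.species_seqs:
        raise KeyError(f"species {species!r} absent from the alignment block")
    cols = block.ref_columns
    ref = np.frombuffer(block.ref_seq.upper().encode(), dtype=np.uint8)[cols]
    spp = np.frombuffer(block.species_seqs[species].upper().encode(), dtype=np.uint8)[cols]
    return (ref == spp) & (spp != ord("-"))


def _runs(mask: np.ndarray, min_len: int, offset: int) -> list[tuple[int, int]]:
    """Maximal True runs of length >= min_len, as half-open intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [
        (offset + s, offset + e) for s, e in zip(starts, ends) if e - s >= min_len
    ]


def _qualifying_bases(match: np.ndarray, window: int, min_identity: float) -> np.ndarray:
    """Bases covered by any window with identity strictly above cutoff."""
    n = match.size
    if n < window:
        return np.zeros(n, dtype=bool)
    csum = np.concatenate([[0], np.cumsum(match)])
    wsum = csum[window:] - csum[:-window]  # window starting at each index
    good = wsum > min_identity * window
    # dilate: base i qualifies if any window start in [i-window+1, i] is good
    gsum = np.concatenate([[0], np.cumsum(good)])
    lo = np.maximum(np.arange(n) - window + 1, 0)
    hi = np.minimum(np.arange(n), good.size - 1)
    return (gsum[hi + 1] - gsum[lo]) > 0


def _refine_run(
    match: np.ndarray, lo: int, hi: int, refine_window: int, min_identity: float
) -> tuple[int, int]:
    """Sharpen a qualifying run to match-anchored boundaries.

    The broad detection window overhangs an identity transition by up to
    half its width. Anchor at the best short window inside the run, grow
    outward while the short window touching the boundary still clears
    the identity cutoff (so isolated lucky matches in the background
    cannot seed a boundary), then snap each boundary to the outermost
    matching base.
    """
    conf = 2 * refine_window  # coarse confirmation span: random background
    # (identity ~0.4) virtually never sustains the cutoff over 2w bases
    while hi - lo >= conf:
        if match[lo] and match[lo : lo + conf].mean() > min_identity:
            break
        lo += 1
    while hi - lo >= conf:
        if match[hi - 1] and match[hi - conf : hi].mean() > min_identity:
            break
        hi -= 1
    # fine stage: a conserved element is locally near-perfect, so demand
    # high identity in the boundary-anchored short window; this stops the
    # coarse boundary from absorbing a few adjacent background matches
    fine = 0.85
    w = refine_window
    while hi - lo >= w:
        if match[lo] and match[lo : lo + w].mean() > fine:
            break
        lo += 1
    while hi - lo >= w:
        if match[hi - 1] and match[hi - w : hi].mean() > fine:
            break
        hi -= 1
    return lo, hi


def species_conserved_regions(
    block: AlignmentBlock,
    species: str,
    window: int = 100,
    min_identity: float = 0.70,
    min_len: int = 100,
    refine_window: int = 10,
) -> list[tuple[int, int]]:
    """Reference intervals where one species clears the identity criterion.

    Slides a window of ``window`` reference-anchored columns at step 1; a
    base qualifies when any covering window beats ``min_identity``. Run
    boundaries are then refined with a ``refine_window``-bp local
    criterion (see :func:`_refine_run`); maximal refined runs at least
    ``min_len`` long are returned as 0-based half-open reference
    intervals.
    """
    match = _match_mask(block, species)
    qual = _qualifying_bases(match, window, min_identity)
    out = []
    for lo, hi in _runs(qual, 1, 0):
        lo, hi = _refine_run(match, lo, hi, refine_window, min_identity)
        if hi - lo >= min_len:
            out.append((block.ref_start + lo, block.ref_start + hi))
    return out


def detect_cnes(
    block: AlignmentBlock,
    exons: list[tuple[int, int]],
    avian_min: int = 10,
    tetrapod_min: int = 3,
    window: int = 100,
    min_identity: float = 0.70,
    min_len: int = 100,
) -> list[CNEInterval]:
    """Conserved noncoding elements per clade.

    Per reference base, counts clade species whose conserved regions cover
    it; exonic bases are masked before the run/length test, so a masked
    fragment must itself reach ``min_len``. Avian and tetrapod elements
    are detected independently and may overlap each other.
    """
    for s, e in exons:
        if e < s:
            raise ValueError(f"malformed exon interval ({s}, {e})")
    n_ref = block.ref_columns.size
    exon_mask = np.zeros(n_ref, dtype=bool)
    for s, e in exons:
        lo = max(0, s - block.ref_start)
        hi = min(n_ref, e - block.ref_start)
        if hi > lo:
            exon_mask[lo:hi] = True

    out: list[CNEInterval] = []
    for clade, threshold in (("avian", avian_min), ("tetrapod", tetrapod_min)):
        names = block.species_in_clade(clade)
        if not names:
            continue
        matches = {s: _match_mask(block, s) for s in names}
        covered = np.zeros(n_ref, dtype=np.int32)
        for s in names:
            for lo, hi in species_conserved_regions(
                block, s, window=window, min_identity=min_identity, min_len=min_len
            ):
                covered[lo - block.ref_start : hi - block.ref_start] += 1
        ok = (covered >= threshold) & ~exon_mask
        for lo, hi in _runs(ok, min_len, 0):
            idents = [
                matches[s][lo:hi].mean()
                for s in names
                if matches[s][lo:hi].mean() > min_identity
            ]
            out.append(
                CNEInterval(
                    start=block.ref_start + lo,
                    end=block.ref_start + hi,
                    clade=clade,
                    supporting_species=int(covered[lo:hi].min()),
                    mean_identity=float(np.mean(idents)) if idents else float("nan"),
                )
            )
    return out


def snps_in_cnes(snp_positions: list[int], cnes: list[CNEInterval]) -> pd.DataFrame:
    """Interval join of SNP positions (0-based) against CNE intervals."""
    rows = []
    for pos in snp_positions:
        for i, cne in enumerate(cnes):
            if cne.start <= pos < cne.end:
                rows.append((pos, i, cne.clade, cne.start, cne.end))
    return pd.DataFrame(rows, columns=["pos", "cne_index", "clade", "cne_start", "cne_end"])


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass
class PWM:
    """Position frequency matrix with Match-style information weights."""

    motif_id: str
    matrix: np.ndarray  # (length, 4) base frequencies, rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (length, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def information(self) -> np.ndarray:
        """Per-position information weight sum_b f ln(4 f)."""
        f = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log(4.0 * f), 0.0)
        return term.sum(axis=1)

    @property
    def core_start(self) -> int:
        """Start of the 5 consecutive highest-information positions."""
        w = min(5, self.length)
        info = self.information
        sums = np.convolve(info, np.ones(w), mode="valid")
        return int(np.argmax(sums))

    def _scores(self, idx: np.ndarray, span: slice) -> float:
        info = self.information[span]
        f = self.matrix[span]
        pos = np.arange(f.shape[0])
        sub = idx[span]
        cur = np.where(sub >= 0, f[pos, np.clip(sub, 0, 3)], f.min(axis=1))
        current = float(info @ cur)
        lo = float(info @ f.min(axis=1))
        hi = float(info @ f.max(axis=1))
        if hi <= lo:
            return 0.0
        return (current - lo) / (hi - lo)

    def score(self, window: str) -> tuple[float, float]:
        """(core_score, matrix_score) for one window of len(self) bases."""
        if len(window) != self.length:
            raise ValueError("window length must equal motif length")
        idx = np.array([_BASE_INDEX.get(b, -1) for b in window.upper()])
        w = min(5, self.length)
        core = self._scores(idx, slice(self.core_start, self.core_start + w))
        matrix = self._scores(idx, slice(0, self.length))
        return core, matrix


def scan_pwm_hits(
    seq: str,
    pwms: list[PWM],
    core_cutoff: float = 0.75,
    matrix_cutoff: float = 0.80,
) -> pd.DataFrame:
    """All PWM hits on both strands of ``seq``.

    Offsets are 0-based window starts on the forward strand; motifs
    longer than the sequence are skipped.
    """
    rows = []
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    for pwm in pwms:
        if pwm.length > n:
            continue
        for strand, s in (("+", seq), ("-", rc)):
            for off in range(n - pwm.length + 1):
                core, matrix = pwm.score(s[off : off + pwm.length])
                if core >= core_cutoff and matrix >= matrix_cutoff:
                    fwd_off = off if strand == "+" else n - pwm.length - off
                    rows.append((pwm.motif_id, fwd_off, strand, core, matrix))
    return pd.DataFrame(
        rows, columns=["motif_id", "offset", "strand", "core_score", "matrix_score"]
    )


def tfbs_gain_loss(
    ref_seq: str,
    alt_seq: str,
    pwms: list[PWM],
    core_cutoff: float = 0.75,
    matrix_cutoff: float = 0.80,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binding sites gained and lost between two alleles of one sequence.

    Both sequences are scanned on both strands; a hit is compared by
    (motif, offset, strand). Returns (gained, lost): gained hits are
    present in alt only, lost hits in ref only.
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError("alleles must be substitution variants of equal length")
    ref_hits = scan_pwm_hits(ref_seq, pwms, core_cutoff, matrix_cutoff)
    alt_hits = scan_pwm_hits(alt_seq, pwms, core_cutoff, matrix_cutoff)
    key = ["motif_id", "offset", "strand"]
    ref_keys = set(map(tuple, ref_hits[key].itertuples(index=False)))
    alt_keys = set(map(tuple, alt_hits[key].itertuples(index=False)))
    gained = alt_hits[[tuple(k) not in ref_keys for k in alt_hits[key].itertuples(index=False)]]
    lost = ref_hits[[tuple(k) not in alt_keys for k in ref_hits[key].itertuples(index=False)]]
    return gained.reset_index(drop=True), lost.reset_index(drop=True)


def read_jaspar_pwms(path) -> list[PWM]:
    """Position frequency matrices from a JASPAR-format text file."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        freqs = counts / counts.sum(axis=1, keepdims=True)
        out.append(PWM(motif_id=m.matrix_id or m.name, matrix=freqs))
    return out


# ---------------------------------------------------------------------------
# Alignment I/O (gapped FASTA + species manifest)


def write_alignment(block: AlignmentBlock, fasta_path, manifest_path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{block.ref_name} start={block.ref_start}\n{block.ref_seq}\n")
        for name, seq in block.species_seqs.items():
            fh.write(f">{name}\n{seq}\n")
    pd.DataFrame(
        {"species": list(block.clades), "clade": list(block.clades.values())}
    ).to_csv(manifest_path, sep="\t", index=False)


def read_alignment(fasta_path, manifest_path) -> AlignmentBlock:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    ref = records[0]
    start = 0
    for token in ref.description.split():
        if token.startswith("start="):
            start = int(token.split("=", 1)[1])
    manifest = pd.read_csv(manifest_path, sep="\t")
    clades = dict(zip(manifest["species"], manifest["clade"]))
    return AlignmentBlock(
        ref_name=ref.id,
        ref_start=start,
        ref_seq=str(ref.seq),
        species_seqs={r.id: str(r.seq) for r in records[1:]},
        clades=clades,
    )


def write_cne_bed(cnes: list[CNEInterval], scaffold: str, path) -> None:
    with open(path, "w") as fh:
        for c in cnes:
            fh.write(f"{scaffold}\t{c.start}\t{c.end}\t{c.clade}:{c.supporting_species}\n")
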
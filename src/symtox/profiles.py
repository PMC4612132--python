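"""Position-specific scoring matrices for toxin domain detection.

MARTX toxins are recognised through their characterised effector domains
(actin cross-linking domain ACD, Rho-GTPase inactivation domain RID,
cysteine protease domain CPD); YD/Rhs proteins through the conserved Rhs
core.  Each domain is modelled as a log-odds PSSM over a background of
average protein amino-acid frequencies, built from a small ungapped seed
alignment.  The shipped seed alignments are synthetic stand-ins (generated
once from random consensi) so the pipeline is exercisable without curated
toxin alignments; users supply real seed alignments the same way.

A profile's score cutoff is calibrated empirically: the 99.9th percentile
of per-sequence maximum window scores over 1,000 random background
proteins, generated from a fixed per-profile seed so the cutoff is a
deterministic property of the profile.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Average amino-acid frequencies of well-annotated proteomes (UniProtKB/
# Swiss-Prot composition statistics), renormalised over the 20 standard
# residues.  Used as the PSSM background and by the sequence simulator.
BACKGROUND_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0228, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0473,
    "S": 0.0664, "T": 0.0534, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
BACKGROUND = np.array([BACKGROUND_FREQS[a] for a in AA])
BACKGROUND /= BACKGROUND.sum()

NULL_CALIBRATION_N = 1000
NULL_PROTEIN_LENGTH = 400
CUTOFF_PERCENTILE = 99.9
MIN_RELATIVE_SCORE = 0.25
PSEUDOCOUNT = 0.5


def encode(seq: str) -> np.ndarray:
    """Map a protein string to integer indices; X and rare codes map to -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


@dataclass
class Pssm:
    name: str
    matrix: np.ndarray            # (length, 20) log-odds, nats
    cutoff: float = field(default=float("nan"))

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def window_scores(self, seq: str) -> np.ndarray:
        """Score of every length-L window of *seq* (empty if seq shorter than L)."""
        idx = encode(seq)
        L = self.length
        n = len(idx) - L + 1
        if n <= 0:
            return np.empty(0)
        # column scores with X (index -1) treated as neutral (0)
        padded = np.vstack([self.matrix.T, np.zeros(self.length)])  # (21, L)^T view
        scores = np.zeros(n)
        for i in range(L):
            scores += padded[idx[i:i + n], i]
        return scores

    def search(self, seq: str) -> list[tuple[int, int, float]]:
        """Windows scoring above the cutoff, overlaps merged keeping the max.

        Returns (start, end, score) with 1-based inclusive aa coordinates.
        """
        scores = self.window_scores(seq)
        above = np.flatnonzero(scores >= self.cutoff)
        if above.size == 0:
            return []
        hits: list[tuple[int, int, float]] = []
        run_start = prev = above[0]
        best = scores[above[0]]
        for w in above[1:]:
            if w <= prev + self.length:  # overlapping windows
                best = max(best, scores[w])
                prev = w
            else:
                hits.append((int(run_start) + 1, int(prev) + self.length, float(best)))
                run_start = prev = w
                best = scores[w]
        hits.append((int(run_start) + 1, int(prev) + self.length, float(best)))
        return hits

    def calibrate(self) -> None:
        """Set the cutoff from the empirical null (seeded by profile name).

        The cutoff is the 99.9th percentile of per-sequence maximum window
        scores on random background proteins, but never less than a fixed
        fraction of the profile's maximum score: a reported domain must
        genuinely resemble the profile, not merely exceed compositional
        noise (which sits near zero on the log-odds scale, far below any
        real domain — a domain diverged 30% still scores ~2/3 of the
        maximum).
        """
        seed = zlib.crc32(self.name.encode()) % (2**31)
        rng = np.random.default_rng(seed)
        maxima = np.empty(NULL_CALIBRATION_N)
        for i in range(NULL_CALIBRATION_N):
            seq_idx = rng.choice(20, size=NULL_PROTEIN_LENGTH, p=BACKGROUND)
            null_seq = "".join(AA[j] for j in seq_idx)
            ws = self.window_scores(null_seq)
            maxima[i] = ws.max() if ws.size else -np.inf
        self.cutoff = max(float(np.percentile(maxima, CUTOFF_PERCENTILE)),
                          MIN_RELATIVE_SCORE * self.max_score)


def build_pssm(name: str, seed_alignment: list[str],
               calibrate: bool = True) -> Pssm:
    """Log-odds PSSM from an ungapped seed alignment with pseudocounts."""
    lengths = {len(s) for s in seed_alignment}
    if len(lengths) != 1:
        raise ValueError(f"profile {name}: seed sequences have unequal lengths")
    L = lengths.pop()
    counts = np.full((L, 20), PSEUDOCOUNT)
    for seq in seed_alignment:
        for pos, residue in enumerate(seq.upper()):
            if residue not in AA_INDEX:
                raise ValueError(
                    f"profile {name}: invalid residue {residue!r} in column {pos + 1}")
            counts[pos, AA_INDEX[residue]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pssm = Pssm(name=name, matrix=np.log(freqs / BACKGROUND))
    if calibrate:
        pssm.calibrate()
    return pssm


# ---------------------------------------------------------------------------
# Plain-text serialisation

def write_pssm(pssm: Pssm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# PSSM {pssm.name}\n# cutoff {pssm.cutoff!r}\n")
        fh.write("pos\t" + "\t".join(AA) + "\n")
        for i, row in enumerate(pssm.matrix, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pssm(path: str | Path) -> Pssm:
    name = Path(path).stem
    cutoff = float("nan")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# PSSM "):
                name = line.split(" ", 2)[2]
            elif line.startswith("# cutoff "):
                cutoff = float(line.split(" ", 2)[2])
            elif line.startswith("pos\t"):
                header = line.split("\t")[1:]
                if header != list(AA):
                    bad = next((c for c in header if c not in AA), header)
                    raise ValueError(f"{path}: malformed profile column {bad!r}")
            elif line and not line.startswith("#"):
                fields = line.split("\t")
                if len(fields) != 21:
                    raise ValueError(
                        f"{path}: row {fields[0]} has {len(fields) - 1} columns, expected 20")
                rows.append([float(v) for v in fields[1:]])
    pssm = Pssm(name=name, matrix=np.array(rows), cutoff=cutoff)
    if np.isnan(cutoff):
        pssm.calibrate()
    return pssm


# ---------------------------------------------------------------------------
# Shipped synthetic seed alignments

def read_seed_alignment(path: str | Path) -> list[str]:
    seqs: list[str] = []
    with open(path) as fh:
        current: list[str] = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                current = []
            else:
                current.append(line)
        if current:
            seqs.append("".join(current))
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return seqs


_DEFAULT_PROFILES: dict[str, Pssm] | None = None


def load_default_profiles() -> dict[str, Pssm]:
    """Load the shipped synthetic ACD/RID/CPD/RHS profiles, calibrated.

    Calibration is deterministic, so the result is cached per process.
    """
    global _DEFAULT_PROFILES
    if _DEFAULT_PROFILES is not None:
        return _DEFAULT_PROFILES
    profiles: dict[str, Pssm] = {}
    root = resources.files("symtox").joinpath("data/profiles")
    for entry in sorted(root.iterdir()):
        if entry.name.endswith(".aln"):
            domain = entry.name.replace("synthetic_", "").replace(".aln", "").upper()
            with resources.as_file(entry) as path:
                profiles[domain] = build_pssm(domain, read_seed_alignment(path))
    if not profiles:
        raise RuntimeError("no shipped profiles found")
    _DEFAULT_PROFILES = profiles
    return profiles
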
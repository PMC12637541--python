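"""Hamming-weight-4 / minimum-distance-4 binary codebooks.

A MERFISH codebook maps gene names (plus non-targeting blank controls) to
fixed-length binary barcodes read out over sequential imaging rounds.  Every
barcode carries exactly four on-bits (Hamming weight 4, HW4) and any two
barcodes differ in at least four positions (minimum Hamming distance 4,
MHD4).  MHD4 guarantees that a single bit error leaves the corrupted word
strictly closer to its true codeword than to any other, enabling
single-bit error correction during decoding.

For two weight-4 words the Hamming distance is ``8 - 2 * |overlap|`` where
``overlap`` counts shared on-bits, so MHD4 is equivalent to "no two
barcodes share more than two on-bits" — the form used by the greedy
construction below.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Codebook",
    "CodebookCapacityError",
    "generate_codebook",
    "mh_balance",
    "validate_codebook",
    "read_codebook_csv",
    "write_codebook_csv",
]

WEIGHT = 4
MIN_DISTANCE = 4


class CodebookCapacityError(ValueError):
    """Raised when the requested number of codes cannot be constructed."""


@dataclass(frozen=True)
class Codebook:
    """An ordered set of named HW4/MHD4 barcodes.

    Parameters
    ----------
    n_bits
        Number of readout bits (imaging rounds x color channels).
    names
        Entry names, genes first by convention; blanks are named
        ``Blank-XX``.
    barcodes
        ``(n_entries, n_bits)`` uint8 array of 0/1 barcode words.
    is_blank
        Boolean flag per entry marking non-targeting blank controls.
    name
        Free-text codebook identifier used in serialization.
    """

    n_bits: int
    names: tuple[str, ...]
    barcodes: np.ndarray
    is_blank: tuple[bool, ...]
    name: str = "codebook"

    def __post_init__(self) -> None:
        barcodes = np.ascontiguousarray(np.asarray(self.barcodes, dtype=np.uint8))
        object.__setattr__(self, "barcodes", barcodes)
        if barcodes.ndim != 2 or barcodes.shape[1] != self.n_bits:
            raise ValueError(
                f"barcodes must be (n_entries, {self.n_bits}), got {barcodes.shape}"
            )
        if len(self.names) != barcodes.shape[0] or len(self.is_blank) != barcodes.shape[0]:
            raise ValueError("names, barcodes and is_blank lengths differ")

    def __len__(self) -> int:
        return self.barcodes.shape[0]

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(n for n, b in zip(self.names, self.is_blank) if not b)

    @property
    def blank_names(self) -> tuple[str, ...]:
        return tuple(n for n, b in zip(self.names, self.is_blank) if b)

    @property
    def n_blanks(self) -> int:
        return sum(self.is_blank)

    def barcode_of(self, name: str) -> np.ndarray:
        return self.barcodes[self.names.index(name)]


def _parity_closed_pool(n_bits: int) -> np.ndarray:
    """All weight-4 words over ``n_bits`` whose on-bit indices XOR to zero.

    These are the weight-4 codewords of the extended Hamming code of the
    next power-of-two length, shortened to ``n_bits``; being codewords of
    a linear code with minimum distance 4 they are pairwise at Hamming
    distance >= 4 (140 words at 16 bits).
    """
    words = []
    for a in range(n_bits):
        for b in range(a + 1, n_bits):
            for c in range(b + 1, n_bits):
                d = a ^ b ^ c
                if c < d < n_bits:
                    w = np.zeros(n_bits, dtype=np.uint8)
                    w[[a, b, c, d]] = 1
                    words.append(w)
    return np.array(words) if words else np.zeros((0, n_bits), dtype=np.uint8)


def generate_codebook(
    n_bits: int,
    n_genes: int,
    n_blanks: int = 0,
    seed: int | None = None,
    *,
    max_restarts: int = 10,
    name: str = "codebook",
    gene_names: list[str] | None = None,
) -> Codebook:
    """Construct a random HW4/MHD4 codebook with blank controls.

    The construction is greedy-randomized: the enumeration of all weight-4
    words over ``n_bits`` is shuffled and a word is accepted iff it shares
    at most two on-bits with every previously accepted word (equivalently,
    Hamming distance >= 4).  Blanks are drawn from the same code, so they
    are structurally indistinguishable from gene barcodes.

    Raises
    ------
    CodebookCapacityError
        If the request cannot be satisfied after ``max_restarts`` shuffles.
    """
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8 for a weight-4 distance-4 code")
    n_total = n_genes + n_blanks
    if n_total < 1:
        raise ValueError("need at least one entry")
    n_words = math.comb(n_bits, WEIGHT)
    if n_total > n_words:
        raise CodebookCapacityError(
            f"{n_total} codes requested but only {n_words} weight-{WEIGHT} "
            f"words exist at {n_bits} bits"
        )
    rng = np.random.default_rng(seed)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n_bits), WEIGHT)),
        dtype=np.int16,
    ).reshape(n_words, WEIGHT)

    accepted = None
    for _ in range(max_restarts):
        order = rng.permutation(n_words)
        candidate = np.zeros((n_total, n_bits), dtype=np.uint8)
        n_acc = 0
        for idx in order:
            word = np.zeros(n_bits, dtype=np.uint8)
            word[combos[idx]] = 1
            if n_acc and (candidate[:n_acc] @ word.astype(np.int32)).max() > WEIGHT - 2:
                continue
            candidate[n_acc] = word
            n_acc += 1
            if n_acc == n_total:
                break
        if n_acc == n_total:
            accepted = candidate
            break
    if accepted is None:
        # Greedy saturates well below the true capacity for small n_bits
        # (e.g. ~100 of the 140 possible words at 16 bits).  Fall back to
        # the parity-closed pool: weight-4 words whose on-bit indices XOR
        # to zero are codewords of the extended Hamming code and hence
        # pairwise distance >= 4, so any subset is a valid codebook.
        pool = _parity_closed_pool(n_bits)
        if len(pool) >= n_total:
            sel = rng.permutation(len(pool))[:n_total]
            accepted = pool[sel]
        else:
            raise CodebookCapacityError(
                f"could not place {n_total} HW{WEIGHT}/MHD{MIN_DISTANCE} codes "
                f"in {n_bits} bits after {max_restarts} randomized attempts "
                f"(structured pool holds only {len(pool)})"
            )

    if gene_names is None:
        width = max(len(str(n_genes)), 3)
        gene_names = [f"gene-{i:0{width}d}" for i in range(n_genes)]
    elif len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    names = tuple(gene_names) + tuple(f"Blank-{i:02d}" for i in range(n_blanks))
    flags = (False,) * n_genes + (True,) * n_blanks
    return Codebook(n_bits=n_bits, names=names, barcodes=accepted, is_blank=flags, name=name)


def _bit_load_cost(barcodes: np.ndarray, prior: np.ndarray) -> float:
    """Squared per-bit expression load: sum_bit (sum of priors on that bit)^2.

    Penalizes co-occurrence of high-expression genes in the same readout
    round; blanks contribute zero load by construction of ``prior``.
    """
    load = prior @ barcodes
    return float(np.dot(load, load))


def mh_balance(
    codebook: Codebook,
    prior: dict[str, float],
    n_steps: int,
    seed: int | None = None,
    *,
    temperature: float = 1.0,
) -> Codebook:
    """Rebalance gene<->barcode assignment by Metropolis-Hastings.

    Proposals swap the barcodes of two uniformly chosen gene entries; a
    move is accepted with probability ``min(1, exp(-dcost / temperature))``
    where the cost is the squared per-bit expression load.  The best state
    visited is returned, so the result never costs more than the input.
    The barcode *set* and all codebook invariants are unchanged — only the
    assignment permutes.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    gene_idx = [i for i, b in enumerate(codebook.is_blank) if not b]
    for i in gene_idx:
        if codebook.names[i] not in prior:
            raise KeyError(f"expression prior missing gene {codebook.names[i]!r}")
    prior_vec = np.zeros(len(codebook))
    for i in gene_idx:
        p = float(prior[codebook.names[i]])
        if p < 0:
            raise ValueError(f"negative prior for {codebook.names[i]!r}")
        prior_vec[i] = p
    if n_steps == 0 or len(gene_idx) < 2:
        return codebook

    rng = np.random.default_rng(seed)
    barcodes = codebook.barcodes.copy()
    cost = _bit_load_cost(barcodes, prior_vec)
    best_barcodes, best_cost = barcodes.copy(), cost
    gene_idx = np.asarray(gene_idx)
    for _ in range(n_steps):
        i, j = rng.choice(gene_idx, size=2, replace=False)
        barcodes[[i, j]] = barcodes[[j, i]]
        new_cost = _bit_load_cost(barcodes, prior_vec)
        delta = new_cost - cost
        if delta <= 0 or rng.random() < math.exp(-delta / temperature):
            cost = new_cost
            if cost < best_cost:
                best_cost, best_barcodes = cost, barcodes.copy()
        else:
            barcodes[[i, j]] = barcodes[[j, i]]  # reject
    return replace(codebook, barcodes=best_barcodes)


@dataclass
class ValidationReport:
    """Violations found in a codebook; empty iff all invariants hold."""

    weight_violations: list[tuple[str, int]] = field(default_factory=list)
    distance_violations: list[tuple[str, str, int]] = field(default_factory=list)
    duplicate_names: list[str] = field(default_factory=list)
    duplicate_barcodes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.weight_violations
            or self.distance_violations
            or self.duplicate_names
            or self.duplicate_barcodes
        )

    def summary(self) -> str:
        if self.ok:
            return "codebook valid"
        lines = []
        for name, w in self.weight_violations:
            lines.append(f"weight {w} != {WEIGHT}: {name}")
        for a, b, d in self.distance_violations:
            lines.append(f"distance {d} < {MIN_DISTANCE}: {a} vs {b}")
        for name in self.duplicate_names:
            lines.append(f"duplicate name: {name}")
        for a, b in self.duplicate_barcodes:
            lines.append(f"duplicate barcode: {a} == {b}")
        return "\n".join(lines)


def validate_codebook(codebook: Codebook) -> ValidationReport:
    """Report every HW4/MHD4/uniqueness violation (never raises)."""
    report = ValidationReport()
    b = codebook.barcodes.astype(np.int32)
    weights = b.sum(axis=1)
    for i, w in enumerate(weights):
        if w != WEIGHT:
            report.weight_violations.append((codebook.names[i], int(w)))
    seen: dict[str, int] = {}
    for i, n in enumerate(codebook.names):
        if n in seen:
            report.duplicate_names.append(n)
        seen[n] = i
    overlap = b @ b.T
    dist = weights[:, None] + weights[None, :] - 2 * overlap
    for i in range(len(codebook)):
        for j in range(i + 1, len(codebook)):
            d = int(dist[i, j])
            if d == 0:
                report.duplicate_barcodes.append((codebook.names[i], codebook.names[j]))
            elif d < MIN_DISTANCE:
                report.distance_violations.append(
                    (codebook.names[i], codebook.names[j], d)
                )
    return report


def write_codebook_csv(codebook: Codebook, path) -> None:
    """Serialize in the MERlin-style CSV dialect.

    Header lines ``version``, ``codebook_name`` and ``bit_names`` precede
    the entry rows ``name, id, barcode``; barcodes are contiguous 0/1
    strings.  Bit index = round * n_colors + color.
    """
    with open(path, "w") as fh:
        fh.write("version, 1.0\n")
        fh.write(f"codebook_name, {codebook.name}\n")
        bit_names = ", ".join(f"bit{i:02d}" for i in range(codebook.n_bits))
        fh.write(f"bit_names, {bit_names}\n")
        fh.write("name, id, barcode\n")
        for i, (n, bc) in enumerate(zip(codebook.names, codebook.barcodes)):
            fh.write(f"{n}, {i}, {''.join(str(int(x)) for x in bc)}\n")


def read_codebook_csv(path) -> Codebook:
    """Parse the MERlin-style dialect written by :func:`write_codebook_csv`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    n_bits = None
    for ln in lines:
        parts = [p.strip() for p in ln.split(",")]
        key = parts[0]
        if key in ("version", "codebook_name"):
            meta[key] = parts[1] if len(parts) > 1 else ""
        elif key == "bit_names":
            n_bits = len(parts) - 1
        elif key == "name":
            continue  # column header row
        else:
            rows.append((parts[0], parts[2]))
    if n_bits is None:
        raise ValueError("missing bit_names header line")
    names = tuple(r[0] for r in rows)
    barcodes = np.array([[int(c) for c in r[1]] for r in rows], dtype=np.uint8)
    flags = tuple(n.startswith("Blank-") for n in names)
    return Codebook(
        n_bits=n_bits,
        names=names,
        barcodes=barcodes,
        is_blank=flags,
        name=meta.get("codebook_name", "codebook"),
    )
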
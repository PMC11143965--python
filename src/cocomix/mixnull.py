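"""Composition-matched virtual cocultures: the mixture null model.

A real SC-FB coculture with SC fraction ``p`` should — absent any heterotypic
interaction — look like a mixture of its two single cultures in that exact
proportion. This module builds such "virtual cocultures" at two levels:

* read level: subsample ``round(p*N)`` reads from the SC FASTQ pool and the
  remainder from the FB pool (default N = 38,500,000 total reads), without
  replacement, into a new FASTQ;
* count level: the same operation on count vectors, either as the exact
  expectation ``round(N * (p*q_SC + (1-p)*q_FB))`` or sampled (multivariate
  hypergeometric, matching the read-level operation in distribution).

Virtual samples are the null against which real cocultures are tested in
:mod:`cocomix.de`.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_composition
from .errors import ConfigError, InsufficientReadsError, ReferenceError_

__all__ = [
    "DEFAULT_TOTAL_READS",
    "MixturePlan",
    "plan_mixture",
    "sample_virtual_reads",
    "mix_counts",
    "build_virtual_cohort",
    "count_fastq_records",
    "count_reads_per_gene",
]

#: total reads per virtual coculture, matching the study's stated depth
DEFAULT_TOTAL_READS = 38_500_000


@dataclass(frozen=True)
class MixturePlan:
    """Deterministic read split for one virtual coculture."""

    total_reads: int
    n_from_sc: int
    n_from_fb: int
    seed: int = 0

    def __post_init__(self):
        if self.n_from_sc + self.n_from_fb != self.total_reads:
            raise ConfigError("read split does not conserve the total")
        if min(self.n_from_sc, self.n_from_fb) < 0:
            raise ConfigError("read quotas must be non-negative")


def plan_mixture(p: float, total_reads: int = DEFAULT_TOTAL_READS, seed: int = 0) -> MixturePlan:
    """Split ``total_reads`` between SC and FB pools at SC fraction ``p``.

    Deterministic round-half-to-even split: ``n_from_sc = round(p * N)``.
    """
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"sc fraction must lie in [0, 1], got {p}")
    if total_reads < 1:
        raise ConfigError("total_reads must be >= 1")
    n_sc = int(round(p * total_reads))
    return MixturePlan(int(total_reads), n_sc, int(total_reads) - n_sc, int(seed))


# ---------------------------------------------------------------------------
# FASTQ streaming


def _open_maybe_gzip(path, mode="rb"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def count_fastq_records(path) -> int:
    """Number of records in a 4-line-per-record FASTQ file."""
    n_lines = 0
    first = None
    with _open_maybe_gzip(path) as fh:
        while chunk := fh.read(8 << 20):
            if first is None and chunk:
                first = chunk[:1]
            n_lines += chunk.count(b"\n")
    if n_lines == 0:
        return 0
    if first != b"@":
        raise ConfigError(f"{path} does not look like FASTQ")
    if n_lines % 4:
        raise ConfigError(f"{path}: line count {n_lines} is not a multiple of 4")
    return n_lines // 4


def _iter_records(path):
    """Yield FASTQ records as 4-tuples of lines (bytes, no trailing newline)."""
    with _open_maybe_gzip(path) as fh:
        tail = b""
        pending: list[bytes] = []
        while chunk := fh.read(8 << 20):
            lines = (tail + chunk).split(b"\n")
            tail = lines.pop()
            pending.extend(lines)
            n_full = len(pending) // 4 * 4
            if n_full:
                it = iter(pending[:n_full])
                yield from zip(it, it, it, it)
                pending = pending[n_full:]
        if tail:
            pending.append(tail)
        if len(pending) % 4:
            raise ConfigError(f"{path}: truncated FASTQ record at end of file")
        it = iter(pending)
        yield from zip(it, it, it, it)


def count_reads_per_gene(path) -> dict[str, int]:
    """Tally reads by the gene id encoded in each read name."""
    counts: dict[str, int] = {}
    for name, _, _, _ in _iter_records(path):
        gene = name[1:].split(b":", 1)[0].split(b" ", 1)[0].decode()
        counts[gene] = counts.get(gene, 0) + 1
    return counts


def _select_records(path, selection: np.ndarray, out_fh) -> None:
    """Stream ``path`` writing record i ``selection[i]`` times (0 or more)."""
    if selection.dtype == bool:
        for rec in itertools.compress(_iter_records(path), selection):
            out_fh.write(b"\n".join(rec) + b"\n")
    else:
        for rec, k in zip(_iter_records(path), selection):
            if k:
                out_fh.write((b"\n".join(rec) + b"\n") * int(k))


def _selection_vector(
    rng: np.random.Generator, pool_size: int, quota: int, with_replacement: bool, label: str
) -> np.ndarray:
    if quota == 0:
        return np.zeros(pool_size, dtype=bool)
    if quota <= pool_size and not with_replacement:
        mask = np.zeros(pool_size, dtype=bool)
        mask[rng.choice(pool_size, size=quota, replace=False, shuffle=False)] = True
        return mask
    if not with_replacement:
        raise InsufficientReadsError(
            f"{label} pool holds {pool_size} reads, fewer than the {quota} requested"
        )
    counts = np.bincount(
        rng.integers(0, pool_size, size=quota), minlength=pool_size
    )
    return counts


def sample_virtual_reads(
    sc_pool,
    fb_pool,
    plan: MixturePlan,
    out_path,
    with_replacement: bool = False,
) -> tuple[int, int]:
    """Write a virtual-coculture FASTQ by subsampling the two single pools.

    Draws ``plan.n_from_sc`` reads uniformly without replacement from the SC
    pool and ``plan.n_from_fb`` from the FB pool (input order preserved),
    writing exactly ``plan.total_reads`` records. A pool smaller than its
    quota raises :class:`InsufficientReadsError` unless ``with_replacement``
    is enabled. Seed-reproducible and byte-deterministic.

    Returns the (SC, FB) pool sizes encountered.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(plan.seed), 7)))
    sizes = []
    with open(out_path, "wb") as out_fh:
        for path, quota, label in (
            (sc_pool, plan.n_from_sc, "SC"),
            (fb_pool, plan.n_from_fb, "FB"),
        ):
            pool_size = count_fastq_records(path)
            sizes.append(pool_size)
            selection = _selection_vector(rng, pool_size, quota, with_replacement, label)
            _select_records(path, selection, out_fh)
    return sizes[0], sizes[1]


# ---------------------------------------------------------------------------
# count-level mixing


def mix_counts(
    sc_counts,
    fb_counts,
    p: float,
    total: int,
    mode: str = "expected",
    seed: int = 0,
    with_replacement: bool = False,
) -> np.ndarray:
    """Mix two count vectors at SC fraction ``p`` to depth ``total``.

    ``expected`` mode returns ``round(total * (p*q_SC + (1-p)*q_FB))`` with
    ``q`` the normalised proportion vectors. ``sampled`` mode draws the read-
    level distribution exactly: a multivariate hypergeometric draw of
    ``round(p*total)`` reads from the SC counts and the remainder from FB
    (multinomial if ``with_replacement``).
    """
    sc = np.asarray(sc_counts, dtype=float)
    fb = np.asarray(fb_counts, dtype=float)
    if sc.shape != fb.shape:
        raise ConfigError("count vectors must share the gene universe")
    if sc.sum() <= 0 or fb.sum() <= 0:
        raise ConfigError("count vectors must each have positive total")
    if not (0.0 <= p <= 1.0):
        raise ConfigError("sc fraction must lie in [0, 1]")
    if total < 1:
        raise ConfigError("total must be >= 1")
    if mode == "expected":
        q = p * sc / sc.sum() + (1.0 - p) * fb / fb.sum()
        return np.rint(total * q).astype(np.int64)
    if mode != "sampled":
        raise ConfigError(f"unknown mode {mode!r}")
    plan = plan_mixture(p, total, seed)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 8)))
    out = np.zeros(sc.shape[0], dtype=np.int64)
    for vec, quota, label in ((sc, plan.n_from_sc, "SC"), (fb, plan.n_from_fb, "FB")):
        ivec = np.rint(vec).astype(np.int64)
        pool = int(ivec.sum())
        if quota == 0:
            continue
        if quota <= pool and not with_replacement:
            out += rng.multivariate_hypergeometric(ivec, quota)
        elif with_replacement:
            out += rng.multinomial(quota, vec / vec.sum())
        else:
            raise InsufficientReadsError(
                f"{label} counts total {pool}, fewer than the {quota} requested"
            )
    return out


def build_virtual_cohort(
    singles: ExpressionMatrix,
    compositions: pd.DataFrame,
    total: int = DEFAULT_TOTAL_READS,
    mode: str = "expected",
    seed: int = 0,
) -> ExpressionMatrix:
    """One virtual-coculture column per composition row.

    Columns are named ``virtual:<coculture_id>``, labelled role="virtual" with
    the pair id of the matching real coculture, in composition-table order.
    """
    validate_composition(compositions)
    columns, meta = {}, []
    for i, row in enumerate(compositions.itertuples(index=False)):
        for ref in (row.sc_culture_id, row.fb_culture_id):
            if ref not in singles.counts.columns:
                raise ReferenceError_(
                    f"composition row {row.coculture_id!r} references missing single {ref!r}"
                )
        vid = f"virtual:{row.coculture_id}"
        columns[vid] = mix_counts(
            singles.counts[row.sc_culture_id].to_numpy(),
            singles.counts[row.fb_culture_id].to_numpy(),
            float(row.sc_fraction),
            int(total),
            mode=mode,
            seed=int(np.random.SeedSequence((int(seed), 9, i)).generate_state(1)[0] % (2**31)),
        )
        meta.append(
            {"sample_id": vid, "role": "virtual", "pair_id": row.coculture_id,
             "sc_culture_id": row.sc_culture_id, "fb_culture_id": row.fb_culture_id}
        )
    counts = pd.DataFrame(columns, index=singles.counts.index, dtype=np.int64)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionMatrix(counts, samples).validate()
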
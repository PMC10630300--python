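"""Shared test helpers: a brute-force counting oracle independent of the
implementation, and a randomized FASTQ instance generator."""

from __future__ import annotations

import numpy as np

from regenscreen.library import SampleEntry, SampleManifest, ShRNALibrary, ShRNARecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        s = random_seq(rng, length)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def random_instance(rng: np.random.Generator, max_reads: int = 50, max_guides: int = 20):
    """A small random screen instance: library, manifest, reads, guide offset.

    Reads mix clean barcode+guide amplicons with mutated, truncated and junk
    reads so that the assigned/unassigned/undemuxed partition is exercised.
    """
    n_guides = int(rng.integers(1, max_guides + 1))
    guide_len = int(rng.integers(6, 13))
    bc_len = int(rng.integers(4, 9))
    n_samples = int(rng.integers(2, 5))
    guides = distinct_seqs(rng, n_guides, guide_len)
    barcodes = distinct_seqs(rng, n_samples, bc_len)

    library = ShRNALibrary(
        [ShRNARecord(f"sh_{i}", f"G{i // 2}", g, "targeting") for i, g in enumerate(guides)]
    )
    entries = [SampleEntry(barcodes[0], "pool", "reference_pool")]
    entries += [
        SampleEntry(barcodes[i], f"rep_{i}", "replicate") for i in range(1, n_samples)
    ]
    manifest = SampleManifest(entries)

    spacer = int(rng.integers(0, 6))
    offset = bc_len + spacer
    n_reads = int(rng.integers(0, max_reads + 1))
    reads = []
    for _ in range(n_reads):
        kind = rng.random()
        if kind < 0.55:  # clean amplicon
            bc = barcodes[rng.integers(0, n_samples)]
            guide = guides[rng.integers(0, n_guides)]
            seq = bc + random_seq(rng, spacer) + guide + random_seq(rng, 3)
        elif kind < 0.75:  # mutated somewhere
            bc = barcodes[rng.integers(0, n_samples)]
            guide = guides[rng.integers(0, n_guides)]
            seq = list(bc + random_seq(rng, spacer) + guide)
            pos = int(rng.integers(0, len(seq)))
            seq[pos] = BASES[(BASES.index(seq[pos]) + 1) % 4]
            seq = "".join(seq)
        elif kind < 0.85:  # too short
            seq = random_seq(rng, int(rng.integers(0, bc_len + 2)))
        else:  # junk
            seq = random_seq(rng, offset + guide_len + 2)
        reads.append(seq)
    return library, manifest, reads, offset


def brute_force_count(reads, library: ShRNALibrary, manifest: SampleManifest, offset: int):
    """Linear-scan oracle: compare every read against every barcode and guide.

    Returns (counts dict (shrna_id, sample_id) -> n, unassigned dict, undemuxed).
    """
    L = library.guide_length
    counts: dict[tuple[str, str], int] = {}
    unassigned: dict[str, int] = {e.sample_id: 0 for e in manifest.entries}
    undemuxed = 0
    for read in reads:
        sample = None
        for e in manifest.entries:
            if len(read) >= len(e.barcode) and read[: len(e.barcode)] == e.barcode:
                sample = e.sample_id
                break
        if sample is None:
            undemuxed += 1
            continue
        shrna = None
        window = read[offset : offset + L]
        if len(window) == L:
            for rec in library:
                if rec.guide_seq == window:
                    shrna = rec.shrna_id
                    break
        if shrna is None:
            unassigned[sample] += 1
        else:
            counts[(shrna, sample)] = counts.get((shrna, sample), 0) + 1
    return counts, unassigned, undemuxed


def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
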
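"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take the dumbest correct route (substring
enumeration, flat scans, exhaustive argmin) and share no code with the
library paths they verify.
"""

from __future__ import annotations

from itertools import accumulate

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


def oracle_cut_positions(sequence: str, enzyme: str) -> set[int]:
    """Positions p such that a cleavage falls between p-1 and p."""
    cuts = set()
    for p in range(1, len(sequence)):
        if sequence[p - 1] in "KR":
            if enzyme == "trypsin" and sequence[p] == "P":
                continue
            cuts.add(p)
    return cuts


def oracle_digest(
    sequence: str,
    enzyme: str,
    max_missed_cleavages: int,
    min_len: int,
    max_len: int,
    collapse_il: bool = True,
) -> set[str]:
    """Enumerate every substring; keep fully tryptic ones within bounds."""
    cuts = oracle_cut_positions(sequence, enzyme)
    boundaries = cuts | {0, len(sequence)}
    # prefix[i] = number of cut positions <= i
    prefix = list(accumulate(1 if p in cuts else 0 for p in range(len(sequence) + 1)))
    out = set()
    for i in range(len(sequence)):
        for j in range(i + 1, len(sequence) + 1):
            if i not in boundaries or j not in boundaries:
                continue
            if not (min_len <= j - i <= max_len):
                continue
            internal = prefix[j - 1] - prefix[i]
            if internal > max_missed_cleavages:
                continue
            pep = sequence[i:j]
            if not set(pep) <= CANONICAL:
                continue
            out.add(pep.replace("I", "L") if collapse_il else pep)
    return out


def oracle_digest_with_internal(sequence: str, enzyme: str, min_len: int,
                                max_len: int) -> list[tuple[str, int]]:
    """All fully tryptic substrings with their internal cut counts."""
    cuts = oracle_cut_positions(sequence, enzyme)
    boundaries = sorted(cuts | {0, len(sequence)})
    prefix = list(accumulate(1 if p in cuts else 0 for p in range(len(sequence) + 1)))
    out = []
    for i in boundaries:
        for j in boundaries:
            if j <= i or not (min_len <= j - i <= max_len):
                continue
            out.append((sequence[i:j], prefix[j - 1] - prefix[i]))
    return out


def oracle_count_psms(psm_peptides, taxon_peptides: dict[int, set]) -> dict[int, int]:
    """Flat per-PSM membership scan."""
    counts = {t: 0 for t in taxon_peptides}
    for pep in psm_peptides:
        for t, peps in taxon_peptides.items():
            if pep in peps:
                counts[t] += 1
    return counts


def oracle_best_per_spectrum(tables):
    """Global hyperscore argmax per spectrum, via one flat scan."""
    best = {}
    for table in tables:
        for psm in table.psms:
            key = (-psm.hyperscore, psm.peptide, psm.chunk_id)
            cur = best.get(psm.spectrum_key)
            if cur is None or key < cur[0]:
                best[psm.spectrum_key] = (key, psm)
    return {k: v[1] for k, v in best.items()}


def oracle_classify(og_row, tscas):
    """Exhaustive argmin over all TSCAs with the documented tie order."""
    rank_order = {"domain": 0, "phylum": 1, "class": 2, "order": 3,
                  "family": 4, "genus": 5}
    scored = [
        (
            sum(abs(int(a) - int(b)) for a, b in zip(og_row, t.array)),
            rank_order[t.rank],
            t.taxid,
            t,
        )
        for t in tscas
    ]
    dist, _, _, winner = min(scored, key=lambda x: x[:3])
    return winner.class_letter, dist, winner
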
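"""Independent test oracles shared between unit and acceptance tests."""

import numpy as np

from homeodyn.hmm import AMINO_ACIDS, STOP_LOG_ODDS, HomeodomainAlignment, ProfileHMM, build_profile

NEG = float("-inf")


def naive_best_score(hmm: ProfileHMM, pep: str) -> float:
    """Local-Viterbi oracle: plain dicts, recurrences written from the model
    definition, no vectorization — an independent second implementation."""

    def em(j, ch):
        if ch == "*":
            return STOP_LOG_ODDS
        if ch == "X":
            return 0.0
        return float(hmm.match_log_odds[j - 1, AMINO_ACIDS.index(ch)])

    def ins(ch):
        return STOP_LOG_ODDS if ch == "*" else 0.0

    n, M = len(pep), hmm.M
    entry = -np.log2(M)
    VM, VI, VD = {}, {}, {}
    best = NEG
    for i in range(1, n + 1):
        for j in range(1, M + 1):
            cands = [entry]
            if j >= 2:
                cands.append(VM.get((i - 1, j - 1), NEG) + hmm.t_mm[j - 1])
                cands.append(VI.get((i - 1, j - 1), NEG) + hmm.t_im[j - 1])
                cands.append(VD.get((i - 1, j - 1), NEG) + hmm.t_dm[j - 1])
            VM[(i, j)] = em(j, pep[i - 1]) + max(cands)
            best = max(best, VM[(i, j)])
        for j in range(1, M):
            VI[(i, j)] = ins(pep[i - 1]) + max(
                VM.get((i - 1, j), NEG) + hmm.t_mi[j],
                VI.get((i - 1, j), NEG) + hmm.t_ii[j],
            )
        for j in range(2, M + 1):
            VD[(i, j)] = max(
                VM.get((i, j - 1), NEG) + hmm.t_md[j - 1],
                VD.get((i, j - 1), NEG) + hmm.t_dd[j - 1],
            )
    return best


def random_model(rng, n_rows=5, width=None) -> ProfileHMM:
    """A small random profile from a random gapped alignment."""
    width = width or int(rng.integers(8, 20))
    rows = []
    for _ in range(n_rows):
        row = [AMINO_ACIDS[rng.integers(20)] for _ in range(width)]
        for k in range(width):
            if rng.random() < 0.15:
                row[k] = "-"
        rows.append("".join(row))
    rows = [("A" if r[0] == "-" else r[0]) + r[1:] for r in rows]
    aln = HomeodomainAlignment(rows=rows, labels=[f"r{i}" for i in range(n_rows)])
    return build_profile(aln)


def random_peptide(rng, n: int, with_specials: bool = True) -> str:
    pep = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))
    if with_specials and rng.random() < 0.2:
        pos = int(rng.integers(n))
        pep = pep[:pos] + str(rng.choice(["*", "X"])) + pep[pos + 1 :]
    return pep
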
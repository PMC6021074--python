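"""Independent straight-line re-implementation of the scoring procedure.

Deliberately shares no code with the package: its own index formulas, its
own neighbor sort, and a direct three-loop transcription of the scoring
rule, used as the ground truth in equivalence tests.
"""

import math
import random


def oracle_index(name, d1, d2):
    i = len(set(d1) & set(d2))
    a, b = len(set(d1)), len(set(d2))
    if name == "jaccard":
        u = len(set(d1) | set(d2))
        return i / u if u else 0.0
    if a == 0 or b == 0:
        return 0.0
    if name == "simpson":
        return i / min(a, b)
    if name == "geometric":
        return i * i / (a * b)
    if name == "cosine":
        return i / math.sqrt(a * b)
    raise ValueError(name)


def oracle_scores(confidences, disease_sets, index_name, k, denominator="effective"):
    """Score every (gene, candidate disease) pair by brute force.

    confidences: {(u, v): int confidence}; disease_sets: {gene: set}.
    """
    adjacency = {}
    for (u, v), c in confidences.items():
        adjacency.setdefault(u, {})[v] = c
        adjacency.setdefault(v, {})[u] = c
    sets = {g: set(disease_sets.get(g, ())) for g in adjacency}
    scores = {}
    for gene in adjacency:
        ranked = sorted(
            adjacency[gene], key=lambda n: (1.0 - adjacency[gene][n] / 1000.0, n)
        )
        selected = ranked[:k]
        denom = len(selected) if denominator == "effective" else k
        if denom == 0:
            continue
        candidates = set()
        for n in selected:
            candidates |= sets[n]
        for d in candidates:
            total = 0.0
            for n in selected:
                if d in sets[n]:
                    total += oracle_index(index_name, sets[gene], sets[n])
            scores[(gene, d)] = 100.0 * total / denom
    return scores


def random_problem(rng: random.Random, max_nodes=30, max_diseases=8):
    """A random small network plus random annotations."""
    n = rng.randint(4, max_nodes)
    genes = [f"g{i:02d}" for i in range(n)]
    confidences = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.25:
                confidences[(genes[i], genes[j])] = rng.randint(901, 1000)
    diseases = [f"d{i}" for i in range(max_diseases)]
    disease_sets = {
        g: {d for d in diseases if rng.random() < 0.3} for g in genes
    }
    return confidences, disease_sets
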
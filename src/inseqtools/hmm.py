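"""Four-state growth-state HMM over ordered TA-site read counts.

Each TA site is assigned one of four growth states by Viterbi decoding:

* ES — essential: insertions are lethal, sites are empty,
* GD — growth defective: insertions strongly depleted,
* NE — no effect (neutral),
* GA — growth advantaged: insertions over-represented.

Emissions are geometric on the read count, ``P(c | s) = theta_s (1 -
theta_s)^c`` with ``theta_s = 1 / (1 + m_s)`` so that ``m_s`` is the state's
mean count.  State means are tied to the library-wide mean read count ``mu``
over insertion-bearing sites: ES uses a small absolute mean (default 0.05),
GD ``mu / 10``, NE ``mu``, GA ``5 mu``.  Transitions are near-diagonal with a
per-step switch probability ``epsilon`` (default 1e-3) shared equally among
the other three states; the initial distribution is uniform.  All recursion
is in log space; ties are broken toward the more impaired state.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mapping import SiteCountTrack
from .reference import GeneModel, ReferenceIndex

ES, GD, NE, GA = "ES", "GD", "NE", "GA"
STATES = (ES, GD, NE, GA)  # severity order: most to least impaired (path ties)
GENE_SEVERITY = (ES, GD, GA, NE)  # tie-break order for gene calls
NO_SITES = "no_sites"

__all__ = [
    "STATES",
    "EmissionModel",
    "HmmConfig",
    "estimate_emissions",
    "viterbi_states",
    "assign_gene_state",
    "assign_all_gene_states",
]


@dataclass
class HmmConfig:
    epsilon: float = 1e-3  # per-step probability of leaving the current state
    m_es: float = 0.05  # absolute ES state mean count

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1 / 3:
            raise ValueError("epsilon must lie in (0, 1/3)")

    def log_transition(self) -> np.ndarray:
        t = np.full((4, 4), self.epsilon / 3)
        np.fill_diagonal(t, 1 - self.epsilon)
        return np.log(t)


@dataclass
class EmissionModel:
    mu: float
    state_means: dict[str, float] = field(default_factory=dict)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([1.0 / (1.0 + self.state_means[s]) for s in STATES])

    def log_emission(self, counts: np.ndarray) -> np.ndarray:
        """(4, n) matrix of log P(count | state)."""
        theta = self.thetas[:, None]
        return np.log(theta) + counts[None, :] * np.log1p(-theta)


def estimate_emissions(track: SiteCountTrack, config: HmmConfig | None = None) -> EmissionModel:
    """Tie state means to ``mu``, the mean count over insertion-bearing sites.

    Fatal on an all-zero track: a library with no signal cannot be decoded.
    """
    config = config or HmmConfig()
    hit = track.counts[track.counts > 0]
    if hit.size == 0:
        raise ValueError("all-zero count track: no library signal")
    mu = float(hit.mean())
    means = {ES: config.m_es, GD: mu / 10.0, NE: mu, GA: 5.0 * mu}
    return EmissionModel(mu=mu, state_means=means)


def _viterbi(counts: np.ndarray, model: EmissionModel, config: HmmConfig) -> tuple[list[str], float]:
    """Viterbi over one replicon.  Returns (state path, max log-probability).

    ``np.argmax`` picks the first maximising index, and STATES is ordered by
    severity, so ties resolve toward the more impaired state.
    """
    n = counts.size
    log_e = model.log_emission(counts)
    log_t = config.log_transition()
    log_pi = np.full(4, np.log(0.25))

    delta = log_pi + log_e[:, 0]
    back = np.zeros((n, 4), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, None] + log_t  # cand[prev, cur]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(4)] + log_e[:, i]
    last = int(np.argmax(delta))
    logp = float(delta[last])
    path = [last]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i][path[-1]]))
    path.reverse()
    return [STATES[s] for s in path], logp


def viterbi_states(
    track: SiteCountTrack,
    index: ReferenceIndex,
    model: EmissionModel | None = None,
    config: HmmConfig | None = None,
) -> list[str]:
    """Per-site state labels aligned to global site ordinals.

    Each replicon is decoded independently; replicons without sites
    contribute nothing.
    """
    config = config or HmmConfig()
    model = model or estimate_emissions(track, config)
    states: list[str] = [NE] * index.n_sites
    for rep_id, sl in index.replicon_slices.items():
        counts = track.counts[sl]
        if counts.size == 0:
            continue
        path, _ = _viterbi(counts, model, config)
        states[sl] = path
    return states


def assign_gene_state(gene: GeneModel, site_states: Sequence[str]) -> str:
    """Modal site state of the gene; ties broken ES > GD > GA > NE.

    Genes with no TA site return ``"no_sites"``.  Callers are expected to
    exclude duplicated genes before phenotype assignment.
    """
    if gene.n_sites == 0:
        return NO_SITES
    tally = Counter(site_states[o] for o in gene.sites)
    best = max(tally.values())
    for s in GENE_SEVERITY:
        if tally.get(s) == best:
            return s
    raise ValueError(f"unknown site states for {gene.locus!r}: {sorted(tally)}")


def assign_all_gene_states(index: ReferenceIndex, site_states: Sequence[str]) -> dict[str, str]:
    return {
        locus: assign_gene_state(gene, site_states)
        for locus, gene in index.genes.items()
    }
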
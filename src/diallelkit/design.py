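"""Half-diallel mating designs and multi-environment trial layouts.

A method-4 diallel crosses ``p`` inbred parents in all ``p(p-1)/2`` unordered
pairs: the F1 hybrids are evaluated, but neither the parents themselves nor
reciprocal crosses.  Trials are laid out as resolvable incomplete-block
(alpha-lattice) designs with ``n_rep`` replicates per environment; the block
randomisation itself is deferred to the trial simulator so that a design
object is a purely deterministic function of its inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


def cross_id(parent1: str, parent2: str) -> str:
    """Canonical entry identifier for the unordered cross parent1 x parent2."""
    return f"{parent1}/{parent2}"


@dataclass(frozen=True)
class DiallelDesign:
    """A half-diallel (Griffing method 4) trial design.

    Attributes
    ----------
    parents : tuple of str
        Parent identifiers, in the order used for cross enumeration.
    crosses : tuple of (str, str)
        All unordered parent pairs ``(i, j)`` with ``i`` before ``j`` in
        lexicographic enumeration order; no selfs, no reciprocals.
    environments : tuple of str
        Environment (site-season) identifiers.
    reps_per_env : int
        Complete replicates of the full entry set within each environment.
    block_size : int
        Plots per incomplete block; the last block of a replicate may be
        short when the block size does not divide the entry count.
    checks : tuple of str
        Optional commercial-check entries, replicated alongside the crosses
        but excluded from any diallel analysis.
    """

    parents: tuple[str, ...]
    crosses: tuple[tuple[str, str], ...]
    environments: tuple[str, ...]
    reps_per_env: int
    block_size: int
    checks: tuple[str, ...] = field(default=())

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    @property
    def entries(self) -> tuple[str, ...]:
        """Cross entries followed by check entries."""
        return tuple(cross_id(a, b) for a, b in self.crosses) + self.checks

    @property
    def n_plots(self) -> int:
        """Total plots over all environments and replicates."""
        return len(self.entries) * self.reps_per_env * len(self.environments)

    def cross_index(self) -> dict[str, tuple[str, str]]:
        """Map entry id -> (parent1, parent2) for cross entries."""
        return {cross_id(a, b): (a, b) for a, b in self.crosses}

    def validate(self) -> None:
        p = self.n_parents
        expected = {tuple(c) for c in itertools.combinations(self.parents, 2)}
        got = set(self.crosses)
        if got != expected:
            raise ValueError(
                "crosses must be exactly the p(p-1)/2 unordered parent pairs "
                f"(expected {len(expected)}, got {len(got)} distinct)"
            )
        if len(self.crosses) != p * (p - 1) // 2:
            raise ValueError("duplicate crosses present")


def make_design(
    p: int,
    n_env: int = 2,
    n_rep: int = 2,
    block_size: int = 10,
    parents: list[str] | None = None,
    environments: list[str] | None = None,
    checks: list[str] | None = None,
) -> DiallelDesign:
    """Construct a half-diallel design for ``p`` parents.

    Parameters mirror the motivating study's layout: 21 parents give 210
    hybrids evaluated in 2 environments with 2 replicates each (840
    experimental plots).  Deterministic given its inputs; crosses are
    enumerated in lexicographic parent order.

    Raises
    ------
    ValueError
        If ``p < 4`` (the method-4 ANOVA has no SCA degrees of freedom below
        that), or any count is non-positive, or ``n_rep < 2`` (residuals in
        an alpha-lattice are unidentifiable with a single replicate).
    """
    if p < 4:
        raise ValueError(f"method-4 diallel analysis needs p >= 4 parents, got {p}")
    if n_env < 1:
        raise ValueError(f"n_env must be >= 1, got {n_env}")
    if n_rep < 2:
        raise ValueError(f"n_rep must be >= 2, got {n_rep}")
    if block_size < 2:
        raise ValueError(f"block_size must be >= 2, got {block_size}")

    if parents is None:
        parents = [f"P{i + 1:02d}" for i in range(p)]
    if len(parents) != p or len(set(parents)) != p:
        raise ValueError("parents must be p distinct identifiers")
    if environments is None:
        environments = [f"E{k + 1}" for k in range(n_env)]
    if len(environments) != n_env:
        raise ValueError("environments must have length n_env")

    crosses = tuple(itertools.combinations(parents, 2))
    design = DiallelDesign(
        parents=tuple(parents),
        crosses=crosses,
        environments=tuple(environments),
        reps_per_env=n_rep,
        block_size=block_size,
        checks=tuple(checks or ()),
    )
    design.validate()
    return design
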
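"""Elementary metabolite unit (EMU) decomposition.

An EMU is a subset of one metabolite's carbon atoms; its mass isotopomer
distribution (MID) can be balanced independently of the rest of the
isotopomer space, which collapses the 2^C-per-species isotopomer system to
a small cascade of linear blocks ordered by EMU size.  The decomposition
here is demand-driven: starting from the measured fragments, producing
reactions are traversed backwards and every source EMU they reference is
added, until the system closes.

Symmetric metabolites (succinate, fumarate) are handled by splitting each
production route into the two molecular orientations at half flux, which
reproduces the positional scrambling a rotationally symmetric intermediate
imposes on downstream labeling.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import ReactionNetwork, Reaction, NetworkError

__all__ = ["EMU", "EMUReaction", "EMUNetwork", "decompose", "convolve"]


@dataclass(frozen=True, order=True)
class EMU:
    """Species id plus a sorted tuple of 1-based carbon positions."""

    species: str
    positions: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(sorted(self.positions)))

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:  # e.g. "MAL.m{1,2,4}"
        return f"{self.species}{{{','.join(map(str, self.positions))}}}"


@dataclass(frozen=True)
class EMUReaction:
    """One production route for ``product``: flux-weighted transfer or convolution.

    ``sources`` holds one EMU for a plain transfer, two or more for a
    condensation (their MIDs convolve).  ``direction`` is +1 for the forward
    direction of ``reaction_id`` and -1 for the reverse of a reversible
    reaction; ``coef`` carries the 0.5 weights of symmetric scrambling and
    any stoichiometric multiplicity.
    """

    product: EMU
    sources: tuple[EMU, ...]
    reaction_id: str
    direction: int = 1
    coef: float = 1.0

    def __post_init__(self):
        if sum(s.size for s in self.sources) != self.product.size:
            raise NetworkError(
                f"EMU reaction size mismatch: {self.product} <- "
                f"{' + '.join(map(str, self.sources))}"
            )


@dataclass
class EMUNetwork:
    """Closed EMU system grouped by size.

    ``emus_by_size[s]`` lists the unknown (balanced) EMUs of size s in
    deterministic order; ``input_emus`` are EMUs of external species whose
    MIDs are prescribed by the tracer protocol.
    """

    emus_by_size: dict[int, list[EMU]]
    reactions: list[EMUReaction]
    input_emus: list[EMU]
    targets: list[EMU]

    @property
    def sizes(self) -> list[int]:
        return sorted(self.emus_by_size)

    @property
    def n_state(self) -> int:
        return sum((s + 1) * len(v) for s, v in self.emus_by_size.items())

    def all_emus(self) -> list[EMU]:
        return [e for s in self.sizes for e in self.emus_by_size[s]]

    def producing(self, emu: EMU) -> list[EMUReaction]:
        return [r for r in self.reactions if r.product == emu]


def convolve(mid_a: Sequence[float], mid_b: Sequence[float]) -> np.ndarray:
    """Convolve two mole-fraction vectors (MID of a joined fragment).

    Both inputs must be nonnegative and sum to 1 within 1e-9; the result has
    length ``len(a) + len(b) - 1`` and again sums to 1.
    """
    a = np.asarray(mid_a, float)
    b = np.asarray(mid_b, float)
    for name, v in (("a", a), ("b", b)):
        if np.any(v < -1e-12):
            raise ValueError(f"mid_{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"mid_{name} does not sum to 1 (sum={v.sum():.3e})")
    return np.convolve(np.clip(a, 0, None), np.clip(b, 0, None))


def _production_routes(
    rxn: Reaction, direction: int
) -> list[tuple[float, list[tuple[str, str]], list[tuple[str, str]]]]:
    """Directed (flux sign, products, reactants) views of an atom-mapped reaction.

    Each entry is ``(coef, product_terms, reactant_terms)`` where terms are
    (species, atom-string) pairs.  For direction=-1 the sides swap.
    """
    if not rxn.has_atom_map:
        return []
    reac = [(t.species, t.atoms) for t in rxn.reactants]
    prod = [(t.species, t.atoms) for t in rxn.products]
    if direction == 1:
        return [(1.0, prod, reac)]
    return [(1.0, reac, prod)]


def _trace_sources(
    emu: EMU,
    atoms_of_product: str,
    reactant_terms: list[tuple[str, str]],
    rxn_id: str,
) -> tuple[EMU, ...]:
    """Map the EMU's positions through one product instance back to reactant EMUs."""
    letters = {atoms_of_product[p - 1] for p in emu.positions}
    sources = []
    found = set()
    for sp, atoms in reactant_terms:
        pos = tuple(i + 1 for i, ch in enumerate(atoms) if ch in letters)
        if pos:
            sources.append(EMU(sp, pos))
            found.update(atoms[i - 1] for i in pos)
    missing = letters - found
    if missing:
        raise NetworkError(
            f"{rxn_id}: atoms {sorted(missing)} of {emu} have no reactant origin"
        )
    return tuple(sorted(sources))


def decompose(
    net: ReactionNetwork,
    targets: Iterable[EMU | tuple[str, Iterable[int]] | str],
) -> EMUNetwork:
    """Minimal closed EMU network reaching the measured fragments.

    ``targets`` accepts :class:`EMU` objects, ``(species, positions)`` pairs,
    or bare species names (meaning the full-molecule fragment).  Raises
    :class:`~picoflux.network.NetworkError` for a target without atom-mapped
    producers, naming the unreachable EMU.
    """
    symmetric = net.symmetric_species()
    external = {n for n, s in net.species.items() if s.external}

    tgt: list[EMU] = []
    for t in targets:
        if isinstance(t, EMU):
            tgt.append(t)
        elif isinstance(t, str):
            n = net.species[t].carbons
            if n == 0:
                raise NetworkError(f"target species {t!r} has no atom map")
            tgt.append(EMU(t, tuple(range(1, n + 1))))
        else:
            sp, pos = t
            tgt.append(EMU(sp, tuple(pos)))
    for e in tgt:
        nc = net.species[e.species].carbons
        if nc == 0:
            raise NetworkError(f"target species {e.species!r} has no atom map")
        if any(p < 1 or p > nc for p in e.positions):
            raise NetworkError(f"target {e} positions outside 1..{nc}")

    emu_rxns: list[EMUReaction] = []
    known: set[EMU] = set()
    inputs: set[EMU] = set()
    queue: deque[EMU] = deque(sorted(set(tgt)))

    while queue:
        emu = queue.popleft()
        if emu in known:
            continue
        known.add(emu)
        if emu.species in external:
            inputs.add(emu)
            continue
        produced = False
        for rxn in net.reactions:
            directions = [1] + ([-1] if rxn.reversible else [])
            for d in directions:
                for coef, prod_terms, reac_terms in _production_routes(rxn, d):
                    instances = [
                        (sp, atoms) for sp, atoms in prod_terms if sp == emu.species
                    ]
                    for _, atoms in instances:
                        orientations = [(coef, atoms)]
                        if emu.species in symmetric:
                            orientations = [
                                (coef * 0.5, atoms),
                                (coef * 0.5, atoms[::-1]),
                            ]
                        for w, at in orientations:
                            sources = _trace_sources(emu, at, reac_terms, rxn.id)
                            emu_rxns.append(
                                EMUReaction(
                                    product=emu,
                                    sources=sources,
                                    reaction_id=rxn.id,
                                    direction=d,
                                    coef=w,
                                )
                            )
                            produced = True
                            for s in sources:
                                if s not in known:
                                    queue.append(s)
        if not produced:
            raise NetworkError(f"EMU {emu} is unreachable: no producing reaction")

    # deduplicate identical routes (symmetric maps can coincide) by summing coefs
    merged: dict[tuple, EMUReaction] = {}
    for r in emu_rxns:
        key = (r.product, r.sources, r.reaction_id, r.direction)
        if key in merged:
            old = merged[key]
            merged[key] = EMUReaction(
                r.product, r.sources, r.reaction_id, r.direction, old.coef + r.coef
            )
        else:
            merged[key] = r
    emu_rxns = sorted(
        merged.values(),
        key=lambda r: (r.product, r.reaction_id, r.direction, r.sources),
    )

    unknown = sorted(e for e in known if e.species not in external)
    by_size: dict[int, list[EMU]] = {}
    for e in unknown:
        by_size.setdefault(e.size, []).append(e)
    for s in by_size:
        by_size[s].sort()
    return EMUNetwork(
        emus_by_size=by_size,
        reactions=emu_rxns,
        input_emus=sorted(inputs),
        targets=tgt,
    )
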
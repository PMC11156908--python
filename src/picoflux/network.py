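"""Compartmentalized metabolic network with carbon atom transitions.

The network model underlying instationary 13C flux analysis: every
carbon-carrying reaction declares how reactant carbons map onto product
carbons, so that isotope propagation can be simulated.  Reactions live in
compartments (chloroplast ``.h``, cytosol ``.c``, mitochondria ``.m``);
the same chemical in two compartments is two distinct species.  External
pools (``.x`` suffix or declared via a ``#!`` directive) are excluded from
the steady-state balance — the inorganic carbon source with its prescribed
labeling time course is the canonical example.

Atom maps use the lowercase-letter convention: ``OAA.m (abcd) -> PEP.c
(abc) + CO2.m (d)`` reads "carbons 1-3 of oxaloacetate become PEP, carbon
4 leaves as CO2".  Letters are 1-based left-to-right positions and each
letter must appear exactly once per side.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import lstsq, null_space
from scipy.optimize import linprog

__all__ = [
    "NetworkError",
    "ParseError",
    "InfeasibleError",
    "Term",
    "Reaction",
    "Species",
    "ReactionNetwork",
    "FluxVector",
    "FreeFluxBasis",
    "parse_network",
    "parse_reaction",
    "write_network",
    "stoichiometric_matrix",
    "free_flux_basis",
    "attach_biomass_sink",
    "positive_solution_exists",
]

COMPARTMENTS = {
    "h": "chloroplast",
    "c": "cytosol",
    "m": "mitochondria",
    "x": "external",
}


class NetworkError(ValueError):
    """Base class for network construction problems."""


class ParseError(NetworkError):
    """Raised when a reaction table row cannot be parsed or is unbalanced."""


class InfeasibleError(NetworkError):
    """Raised when no flux vector satisfies the steady-state constraints."""

    def __init__(self, message: str, violated_species: Sequence[str] = ()):
        super().__init__(message)
        self.violated_species = list(violated_species)


@dataclass(frozen=True)
class Term:
    """One species instance in a reaction equation.

    ``atoms`` is the atom-map string for this instance (``None`` for sink
    coefficients that aggregate polymers).  A species occurring twice on a
    side (e.g. the two 3-phosphoglycerate molecules produced by RuBisCO)
    is two Terms.
    """

    species: str
    coef: float = 1.0
    atoms: str | None = None


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[Term, ...]
    products: tuple[Term, ...]
    reversible: bool = False
    kind: str = "internal"  # internal | transport | sink | source
    pathway: str = ""
    notes: str = ""

    @property
    def has_atom_map(self) -> bool:
        terms = self.reactants + self.products
        return bool(terms) and all(t.atoms is not None for t in terms)

    def equation(self) -> str:
        def side(terms: tuple[Term, ...]) -> str:
            parts = []
            for t in terms:
                s = t.species if t.coef == 1 else f"{t.coef:g} {t.species}"
                if t.atoms is not None:
                    s += f" ({t.atoms})"
                parts.append(s)
            return " + ".join(parts)

        return f"{side(self.reactants)} -> {side(self.products)}"


@dataclass(frozen=True)
class Species:
    name: str
    carbons: int
    compartment: str | None
    external: bool = False
    symmetric: bool = False


@dataclass
class ReactionNetwork:
    """Parsed, validated reaction network.

    ``balanced_species`` are the internal metabolites subject to the
    steady-state constraint S·v = b; externals (label source, biomass
    classes) are excluded.  ``dilution_species`` lists measured metabolites
    that carry an inactive-pool dilution parameter.
    """

    species: dict[str, Species]
    reactions: list[Reaction]
    dilution_species: list[str] = field(default_factory=list)
    fixed_sink_fluxes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ParseError(f"duplicated reaction id(s): {', '.join(sorted(dup))}")

    @property
    def balanced_species(self) -> list[str]:
        return sorted(n for n, s in self.species.items() if not s.external)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def symmetric_species(self) -> set[str]:
        return {n for n, s in self.species.items() if s.symmetric}


@dataclass
class FluxVector:
    """Net + exchange flux assignment, mmol gDW^-1 h^-1.

    Exchange fluxes are nonnegative and zero for irreversible reactions.
    The forward/backward decomposition used by the labeling simulator is
    ``vf = exch + max(net, 0)``, ``vb = exch + max(-net, 0)``.
    """

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def forward(self, rxn_id: str) -> float:
        return self.exchange.get(rxn_id, 0.0) + max(self.net.get(rxn_id, 0.0), 0.0)

    def backward(self, rxn_id: str) -> float:
        return self.exchange.get(rxn_id, 0.0) + max(-self.net.get(rxn_id, 0.0), 0.0)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.net.get(r, 0.0) for r in order], float)

    def scaled(self, factor: float) -> "FluxVector":
        return FluxVector(
            net={k: v * factor for k, v in self.net.items()},
            exchange={k: v * factor for k, v in self.exchange.items()},
        )


# ---------------------------------------------------------------------------
# parsing

_TERM_RE = re.compile(
    r"^\s*(?:(?P<coef>\d+(?:\.\d+)?)\s+)?(?P<species>[A-Za-z0-9_]+(?:\.[a-z])?)"
    r"\s*(?:\((?P<atoms>[a-zA-Z]+)\))?\s*$"
)


def _parse_side(text: str, row: str) -> tuple[Term, ...]:
    text = text.strip()
    if not text:
        return ()
    terms = []
    for chunk in text.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise ParseError(f"{row}: cannot parse term {chunk.strip()!r}")
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        terms.append(Term(m.group("species"), coef, m.group("atoms")))
    return tuple(terms)


def _compartment_of(name: str) -> str | None:
    if "." in name:
        tag = name.rsplit(".", 1)[1]
        return COMPARTMENTS.get(tag, tag)
    return None


def _is_external_name(name: str) -> bool:
    return name.endswith(".x")


def _check_atom_balance(rxn: Reaction) -> None:
    """Atom conservation: product letters are a permutation of reactant letters."""
    mapped_r = [t for t in rxn.reactants if t.atoms is not None]
    mapped_p = [t for t in rxn.products if t.atoms is not None]
    if not mapped_r and not mapped_p:
        return
    for side_name, terms in (("reactant", mapped_r), ("product", mapped_p)):
        letters = [ch for t in terms for ch in t.atoms]  # type: ignore[union-attr]
        dup = [ch for ch, c in Counter(letters).items() if c > 1]
        if dup:
            raise ParseError(
                f"{rxn.id}: atom label(s) {', '.join(sorted(dup))} used twice on "
                f"the {side_name} side"
            )
    r_letters = Counter(ch for t in mapped_r for ch in t.atoms)  # type: ignore[union-attr]
    p_letters = Counter(ch for t in mapped_p for ch in t.atoms)  # type: ignore[union-attr]
    if rxn.kind not in ("sink",) and mapped_r and mapped_p and r_letters != p_letters:
        raise ParseError(
            f"{rxn.id}: carbon-count mismatch (reactant atoms "
            f"{''.join(sorted(r_letters.elements()))!r} vs product atoms "
            f"{''.join(sorted(p_letters.elements()))!r})"
        )


def _infer_kind(rxn: Reaction, externals: set[str]) -> str:
    if not rxn.products:
        return "sink"
    if not rxn.reactants:
        return "source"
    r_ext = all(t.species in externals or _is_external_name(t.species) for t in rxn.reactants)
    p_ext = all(t.species in externals or _is_external_name(t.species) for t in rxn.products)
    if r_ext and not p_ext:
        return "source"
    if p_ext and not r_ext:
        return "sink"
    if (
        len(rxn.reactants) == 1
        and len(rxn.products) == 1
        and rxn.reactants[0].species.split(".")[0] == rxn.products[0].species.split(".")[0]
        and rxn.reactants[0].species != rxn.products[0].species
    ):
        return "transport"
    return "internal"


def parse_reaction(
    rxn_id: str,
    equation: str,
    reversible: bool = False,
    pathway: str = "",
    notes: str = "",
    externals: set[str] | None = None,
) -> Reaction:
    """Parse a single equation string like ``"A (ab) -> B (b) + C (a)"``."""
    if "->" not in equation:
        raise ParseError(f"{rxn_id}: equation lacks '->'")
    lhs, rhs = equation.split("->", 1)
    rxn = Reaction(
        id=rxn_id,
        reactants=_parse_side(lhs, rxn_id),
        products=_parse_side(rhs, rxn_id),
        reversible=reversible,
        pathway=pathway,
        notes=notes,
    )
    rxn = replace(rxn, kind=_infer_kind(rxn, externals or set()))
    _check_atom_balance(rxn)
    return rxn


_TRUE = {"1", "true", "yes", "y", "r", "reversible"}


def parse_network(source) -> ReactionNetwork:
    """Parse a delimited reaction table into a validated network.

    ``source`` may be a path, a file object, or the table text itself.
    Lines starting with ``#!`` are directives::

        #! external: CO2.x
        #! symmetric: SUC.m, FUM.m
        #! dilution: PGA.h, AKG.m

    Data rows are tab- (or multi-space-) separated:
    ``id<TAB>equation<TAB>reversible[<TAB>pathway[<TAB>notes]]``.
    Carbon counts are inferred from atom maps and checked for consistency
    across reactions; a mismatch names the offending row.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if text and "\n" not in text and "->" not in text:
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()

    externals: set[str] = set()
    symmetric: set[str] = set()
    dilution: list[str] = []
    rows: list[tuple[str, str, bool, str, str]] = []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if line.startswith("#!"):
                directive = line[2:].strip()
                if ":" not in directive:
                    raise ParseError(f"line {lineno}: malformed directive {line!r}")
                key, val = directive.split(":", 1)
                names = [v.strip() for v in re.split(r"[,\s]+", val.strip()) if v.strip()]
                key = key.strip().lower()
                if key == "external":
                    externals.update(names)
                elif key == "symmetric":
                    symmetric.update(names)
                elif key == "dilution":
                    dilution.extend(names)
                else:
                    raise ParseError(f"line {lineno}: unknown directive {key!r}")
            continue
        if line.lower().startswith("id\t") or line.lower().startswith("id,"):
            continue  # header
        fields = re.split(r"\t|  +", line)
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 2:
            # allow "id: equation" shorthand
            m = re.match(r"^([A-Za-z0-9_]+)\s*:\s*(.+)$", line)
            if not m:
                raise ParseError(f"line {lineno}: expected id and equation in {line!r}")
            fields = [m.group(1), m.group(2)]
        rxn_id, equation = fields[0], fields[1]
        if ":" in rxn_id:
            rxn_id = rxn_id.rstrip(":")
        rev = fields[2].lower() in _TRUE if len(fields) > 2 else False
        pathway = fields[3] if len(fields) > 3 else ""
        notes = fields[4] if len(fields) > 4 else ""
        rows.append((rxn_id, equation, rev, pathway, notes))

    reactions = [
        parse_reaction(rid, eq, rev, pathway, notes, externals)
        for rid, eq, rev, pathway, notes in rows
    ]
    species = _collect_species(reactions, externals, symmetric)
    net = ReactionNetwork(species=species, reactions=reactions, dilution_species=dilution)
    for sp in dilution:
        if sp not in species:
            raise ParseError(f"dilution declared for unknown species {sp!r}")
    return net


def _collect_species(
    reactions: Iterable[Reaction], externals: set[str], symmetric: set[str]
) -> dict[str, Species]:
    carbons: dict[str, int] = {}
    seen: dict[str, str] = {}  # species -> reaction that set the carbon count
    names: list[str] = []
    for rxn in reactions:
        for term in rxn.reactants + rxn.products:
            if term.species not in carbons:
                names.append(term.species)
            if term.atoms is not None:
                n = len(term.atoms)
                prev = carbons.get(term.species)
                if prev is not None and prev != n:
                    raise ParseError(
                        f"{rxn.id}: carbon-count mismatch for {term.species} "
                        f"({n} here vs {prev} in {seen[term.species]})"
                    )
                carbons[term.species] = n
                seen.setdefault(term.species, rxn.id)
            else:
                carbons.setdefault(term.species, 0)
    return {
        name: Species(
            name=name,
            carbons=carbons.get(name, 0),
            compartment=_compartment_of(name),
            external=name in externals or _is_external_name(name),
            symmetric=name in symmetric,
        )
        for name in names
    }


def write_network(net: ReactionNetwork, path_or_buf=None) -> str | None:
    """Write the network back out in the same TSV dialect ``parse_network`` reads."""
    lines = []
    ext = sorted(n for n, s in net.species.items() if s.external)
    sym = sorted(net.symmetric_species())
    if ext:
        lines.append("#! external: " + ", ".join(ext))
    if sym:
        lines.append("#! symmetric: " + ", ".join(sym))
    if net.dilution_species:
        lines.append("#! dilution: " + ", ".join(net.dilution_species))
    lines.append("id\tequation\treversible\tpathway\tnotes")
    for r in net.reactions:
        lines.append(
            "\t".join(
                [r.id, r.equation(), "1" if r.reversible else "0", r.pathway, r.notes]
            )
        )
    text = "\n".join(lines) + "\n"
    if path_or_buf is None:
        return text
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(text)
    return None


# ---------------------------------------------------------------------------
# stoichiometry and flux parameterization


def stoichiometric_matrix(
    net: ReactionNetwork,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Signed stoichiometric matrix over balanced species x reactions.

    Returns ``(S, species, reaction_ids)``; externals are excluded from the
    rows.  An empty network yields a 0x0 matrix.
    """
    species = net.balanced_species
    rxns = net.reaction_ids
    S = np.zeros((len(species), len(rxns)))
    index = {s: i for i, s in enumerate(species)}
    for j, rxn in enumerate(net.reactions):
        for term in rxn.reactants:
            if term.species in index:
                S[index[term.species], j] -= term.coef
        for term in rxn.products:
            if term.species in index:
                S[index[term.species], j] += term.coef
    return S, species, rxns


@dataclass
class FreeFluxBasis:
    """Affine parameterization v = v0 + N @ theta of the steady-state manifold.

    ``free_reactions`` names the anchor reactions whose net fluxes serve as
    the free coordinates theta (when an anchored basis was requested);
    otherwise theta is an abstract null-space coordinate.
    """

    v0: np.ndarray
    N: np.ndarray
    reaction_ids: list[str]
    free_reactions: list[str] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def flux_array(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, float))
        return self.v0 + self.N @ theta if self.dim else self.v0.copy()

    def flux_vector(self, theta: np.ndarray, exchange: Mapping[str, float] | None = None) -> FluxVector:
        v = self.flux_array(theta)
        return FluxVector(
            net=dict(zip(self.reaction_ids, v.tolist())),
            exchange=dict(exchange or {}),
        )


def free_flux_basis(
    net: ReactionNetwork,
    fixed_fluxes: Mapping[str, float] | None = None,
    rhs: Mapping[str, float] | None = None,
    anchored: bool = True,
    prefer: Sequence[str] = (),
    tol: float = 1e-9,
) -> FreeFluxBasis:
    """Particular solution + null-space basis of S·v = b with fixed entries.

    ``fixed_fluxes`` pins named reactions (typically biomass sinks scaled by
    the growth rate); ``rhs`` supplies per-species demands b (default 0).
    With ``anchored=True`` the free coordinates are the net fluxes of a
    deterministic set of anchor reactions (non-pivot columns of the
    constraint system), which gives free parameters with physical units and
    simple box bounds.  ``prefer`` lists reaction ids tried first as
    anchors, so that a branch of scientific interest (e.g. the
    AKG-to-succinate step) becomes a free coordinate directly.

    Raises :class:`InfeasibleError` when the constraints are inconsistent,
    listing the violated species.
    """
    S, species, rxns = stoichiometric_matrix(net)
    fixed = dict(net.fixed_sink_fluxes)
    if fixed_fluxes:
        fixed.update(fixed_fluxes)
    for rid in fixed:
        if rid not in rxns:
            raise NetworkError(f"fixed flux for unknown reaction {rid!r}")
    b = np.zeros(len(species))
    if rhs:
        for sp, val in rhs.items():
            if sp not in species:
                raise NetworkError(f"demand on unknown species {sp!r}")
            b[species.index(sp)] = val

    n = len(rxns)
    rows = [S]
    vals = [b]
    for rid, val in sorted(fixed.items()):
        e = np.zeros(n)
        e[rxns.index(rid)] = 1.0
        rows.append(e[None, :])
        vals.append(np.array([val]))
    A = np.vstack(rows) if rows else np.zeros((0, n))
    bb = np.concatenate(vals) if vals else np.zeros(0)

    if n == 0:
        return FreeFluxBasis(np.zeros(0), np.zeros((0, 0)), [], [])

    v0, *_ = lstsq(A, bb, lapack_driver="gelsd")
    resid = A @ v0 - bb
    if np.linalg.norm(resid, np.inf) > max(tol, 1e-8 * (1 + np.linalg.norm(bb))):
        bad = [species[i] for i in range(len(species)) if abs(resid[i]) > tol]
        raise InfeasibleError(
            "steady-state constraints are inconsistent"
            + (f" (violated species: {', '.join(bad)})" if bad else ""),
            violated_species=bad,
        )
    NS = null_space(A, rcond=1e-10)

    if not anchored or NS.shape[1] == 0:
        return FreeFluxBasis(v0, NS, rxns, [])

    # choose anchor reactions: greedy selection of columns (in reaction order)
    # that are linearly independent within the null space row span
    k = NS.shape[1]
    anchors: list[int] = []
    basis_rows: list[np.ndarray] = []
    order = [rxns.index(r) for r in prefer if r in rxns]
    order += [j for j in range(n) if j not in order]
    for j in order:
        row = NS[j]
        if np.linalg.norm(row) < 1e-10:
            continue
        if basis_rows:
            B = np.vstack(basis_rows)
            proj = row - B.T @ np.linalg.lstsq(B.T, row, rcond=None)[0]
        else:
            proj = row
        if np.linalg.norm(proj) > 1e-8:
            anchors.append(j)
            basis_rows.append(row)
        if len(anchors) == k:
            break
    # re-express so that theta_i equals the net flux of anchor reaction i
    M = NS[anchors, :]  # k x k, invertible by construction
    T = np.linalg.solve(M, np.eye(k))
    N_anchor = NS @ T
    v0_anchor = v0 - N_anchor @ v0[anchors]
    return FreeFluxBasis(v0_anchor, N_anchor, rxns, [rxns[j] for j in anchors])


def attach_biomass_sink(
    net: ReactionNetwork,
    demands: Mapping[str, Mapping[str, float]],
    growth_rate: float | None = None,
) -> ReactionNetwork:
    """Append one sink reaction per macromolecule class.

    ``demands`` maps class name -> {precursor species: mmol per gDW biomass}.
    When ``growth_rate`` (h^-1) is given, each sink's flux is fixed at mu so
    that precursor drain = coefficient x mu, in mmol gDW^-1 h^-1; a zero
    growth rate therefore zeroes every sink flux.
    """
    new_rxns = list(net.reactions)
    fixed = dict(net.fixed_sink_fluxes)
    species = dict(net.species)
    for cls in sorted(demands):
        coeffs = demands[cls]
        terms = []
        for sp in sorted(coeffs):
            if sp not in net.species:
                raise NetworkError(f"biomass demand on unknown species {sp!r}")
            if coeffs[sp] < 0:
                raise NetworkError(f"negative demand for {sp!r} in class {cls!r}")
            if coeffs[sp] > 0:
                terms.append(Term(sp, float(coeffs[sp])))
        if not terms:
            continue
        rid = f"sink_{cls}"
        new_rxns.append(
            Reaction(
                id=rid,
                reactants=tuple(terms),
                products=(),
                reversible=False,
                kind="sink",
                pathway="biomass",
            )
        )
        if growth_rate is not None:
            if growth_rate < 0:
                raise NetworkError("growth rate must be nonnegative")
            fixed[rid] = float(growth_rate)
    out = ReactionNetwork(
        species=species,
        reactions=new_rxns,
        dilution_species=list(net.dilution_species),
        fixed_sink_fluxes=fixed,
    )
    return out


def positive_solution_exists(
    net: ReactionNetwork,
    min_flux: float = 1e-3,
    max_flux: float = 1e3,
) -> bool:
    """Linear-programming check that a strictly positive steady flux exists.

    Every reaction (in its declared forward direction) must be able to carry
    at least ``min_flux`` simultaneously with S·v = 0.  Fixed sink fluxes are
    ignored here; this is a structural sanity check on shipped networks.
    """
    S, _, rxns = stoichiometric_matrix(net)
    if not rxns:
        return True
    res = linprog(
        c=np.zeros(len(rxns)),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=[(min_flux, max_flux)] * len(rxns),
        method="highs",
    )
    return bool(res.success)


def theta_bounds_lp(
    basis: FreeFluxBasis,
    net: ReactionNetwork,
    max_flux: float = 50.0,
) -> list[tuple[float, float]]:
    """LP-derived feasible box for the free coordinates.

    Minimizes/maximizes each theta_i subject to v = v0 + N theta staying in
    [0, max_flux] for irreversible reactions and [-max_flux, max_flux] for
    reversible ones.  Used to draw random multi-start initial fluxes.
    """
    rev = {r.id: r.reversible for r in net.reactions}
    lb = np.array([-max_flux if rev.get(rid, False) else 0.0 for rid in basis.reaction_ids])
    ub = np.full(len(basis.reaction_ids), max_flux)
    k = basis.dim
    out = []
    # constraints: lb - v0 <= N theta <= ub - v0
    A = np.vstack([basis.N, -basis.N])
    b = np.concatenate([ub - basis.v0, basis.v0 - lb])
    for i in range(k):
        c = np.zeros(k)
        c[i] = 1.0
        lo = linprog(c, A_ub=A, b_ub=b, bounds=[(None, None)] * k, method="highs")
        hi = linprog(-c, A_ub=A, b_ub=b, bounds=[(None, None)] * k, method="highs")
        if not (lo.success and hi.success):
            raise InfeasibleError("no feasible flux region for the free coordinates")
        out.append((float(lo.fun), float(-hi.fun)))
    return out
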
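"""Semantic reaction-network model and the toy model-text grammar.

The in-memory model is purely topological: species, reactions with role-tagged
participants, and compartments.  Rate laws, units and events are out of scope —
geometry and styling only ever need to know *what connects to what*.

The text grammar accepted by :func:`parse_model` is the small Antimony-like
subset used throughout the worked examples::

    J1: Pyr + NAD + CoA -> CO2 + NADH + AcCoA;
    default_compartment is "TCA Cycle";

i.e. zero or more irreversible reaction lines ``ID: term (+ term)* -> term
(+ term)*;`` where a term is ``[coefficient] SpeciesId``, plus one optional
``default_compartment is "Name";`` statement.  Both straight and typographic
quote characters are accepted, because published listings routinely carry
typographic quotes.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .errors import ModelParseError, ValidationError

ROLES = ("reactant", "product", "modifier")

DEFAULT_COMPARTMENT_ID = "default_compartment"

#: The TCA-cycle demonstration model (pyruvate dehydrogenase J1 feeding the
#: eight core cycle reactions J2..J9).
TCA_MODEL_TEXT = """\
J1: Pyr + NAD + CoA -> CO2 + NADH + AcCoA;
J2: Oxalo + AcCoA + H2O -> CoA + Cit;
J3: Cit -> IsoCit;
J4: IsoCit + NAD -> CO2 + NADH + aKG;
J5: aKG + NAD + CoA -> CO2 + NADH + SCoA;
J6: SCoA + GDP + Pi -> CoA + GTP + Succ;
J7: Succ + FAD -> FADH2 + Fum;
J8: Fum + H2O -> Mal;
J9: Mal + NAD -> NADH + Oxalo;
default_compartment is "TCA Cycle";
"""


@dataclass
class Species:
    id: str
    name: str
    compartment_id: str


@dataclass
class Participant:
    species_id: str
    role: str  # one of ROLES
    stoichiometry: float = 1.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"participant role must be one of {ROLES}, got {self.role!r}")
        if not self.stoichiometry > 0:
            raise ValueError("stoichiometry must be positive")


@dataclass
class Reaction:
    id: str
    participants: list[Participant] = field(default_factory=list)

    def by_role(self, role: str) -> list[Participant]:
        return [p for p in self.participants if p.role == role]

    @property
    def reactants(self) -> list[Participant]:
        return self.by_role("reactant")

    @property
    def products(self) -> list[Participant]:
        return self.by_role("product")

    @property
    def modifiers(self) -> list[Participant]:
        return self.by_role("modifier")


@dataclass
class Network:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: list[tuple[str, str]] = field(default_factory=list)  # (id, name)

    def get_species(self, species_id: str) -> Species:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(species_id)

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def validate(self) -> None:
        """Check referential integrity; raise ValidationError listing offenders."""
        errors: list[tuple[str, str]] = []
        if not self.compartments:
            errors.append(("", "network has no compartment"))
        comp_ids = {cid for cid, _ in self.compartments}
        seen: set[str] = set()
        for s in self.species:
            if not s.id:
                errors.append(("", "species with empty id"))
            if s.id in seen:
                errors.append((s.id, "duplicate species id"))
            seen.add(s.id)
            if s.compartment_id not in comp_ids:
                errors.append((s.id, f"unknown compartment {s.compartment_id!r}"))
        species_ids = {s.id for s in self.species}
        rseen: set[str] = set()
        for r in self.reactions:
            if r.id in rseen:
                errors.append((r.id, "duplicate reaction id"))
            rseen.add(r.id)
            if not r.participants:
                errors.append((r.id, "reaction has no participants"))
            for p in r.participants:
                if p.species_id not in species_ids:
                    errors.append((r.id, f"unknown species {p.species_id!r}"))
        if errors:
            raise ValidationError(errors)


# --- grammar ---------------------------------------------------------------

# straight + typographic quotes
_QUOTES = "\"“”‘’'"
_COMP_RE = re.compile(
    rf"^default_compartment\s+is\s+[{_QUOTES}](?P<name>[^{_QUOTES}]*)[{_QUOTES}]$"
)
_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _parse_term(term: str, line_no: int) -> tuple[float, str]:
    parts = term.split()
    if len(parts) == 1:
        coef, sid = 1.0, parts[0]
    elif len(parts) == 2:
        try:
            coef = float(parts[0])
        except ValueError:
            raise ModelParseError(f"bad coefficient {parts[0]!r}", line_no) from None
        sid = parts[1]
    else:
        raise ModelParseError(f"bad term {term!r}", line_no)
    if not _ID_RE.match(sid):
        raise ModelParseError(f"bad species id {sid!r}", line_no)
    if coef <= 0:
        raise ModelParseError(f"coefficient must be positive in {term!r}", line_no)
    return coef, sid


def parse_model(text: str) -> Network:
    """Parse the toy reaction grammar into a :class:`Network`.

    A default compartment is always synthesized (named by the
    ``default_compartment is "..."`` statement when present).  Species are
    created in order of first appearance; participant declaration order is
    preserved within each reaction.
    """
    reactions: list[Reaction] = []
    species_order: list[str] = []
    species_set: set[str] = set()
    comp_name: str | None = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "//")):
            continue
        if not line.endswith(";"):
            raise ModelParseError("statement must end with ';'", line_no)
        stmt = line[:-1].strip()
        m = _COMP_RE.match(stmt)
        if m:
            if comp_name is not None:
                raise ModelParseError("duplicate default_compartment statement", line_no)
            comp_name = m.group("name")
            continue
        if ":" not in stmt:
            raise ModelParseError(f"malformed statement {stmt!r}", line_no)
        rid, _, body = stmt.partition(":")
        rid = rid.strip()
        if not _ID_RE.match(rid):
            raise ModelParseError(f"bad reaction id {rid!r}", line_no)
        if any(r.id == rid for r in reactions):
            raise ModelParseError(f"duplicate reaction id {rid!r}", line_no)
        if "->" not in body:
            raise ModelParseError("reaction must contain '->'", line_no)
        lhs, _, rhs = body.partition("->")
        participants: list[Participant] = []
        for side, role in ((lhs, "reactant"), (rhs, "product")):
            terms = [t.strip() for t in side.split("+")]
            if terms == [""]:
                raise ModelParseError("empty participant list", line_no)
            for term in terms:
                if not term:
                    raise ModelParseError("empty term", line_no)
                coef, sid = _parse_term(term, line_no)
                participants.append(Participant(sid, role, coef))
                if sid not in species_set:
                    species_set.add(sid)
                    species_order.append(sid)
        reactions.append(Reaction(rid, participants))

    comp_id = DEFAULT_COMPARTMENT_ID
    network = Network(
        species=[Species(sid, sid, comp_id) for sid in species_order],
        reactions=reactions,
        compartments=[(comp_id, comp_name if comp_name is not None else comp_id)],
    )
    network.validate()
    return network


def _format_coef(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(c)


def serialize_model(network: Network) -> str:
    """Write a Network back to the toy grammar (inverse of :func:`parse_model`).

    Only networks expressible in the grammar round-trip exactly: one
    compartment, no modifiers, species named by their ids.
    """
    lines = []
    for r in network.reactions:
        def side(role: str) -> str:
            terms = []
            for p in r.by_role(role):
                c = "" if p.stoichiometry == 1 else _format_coef(p.stoichiometry) + " "
                terms.append(c + p.species_id)
            return " + ".join(terms)

        lines.append(f"{r.id}: {side('reactant')} -> {side('product')};")
    if network.compartments:
        lines.append(f'default_compartment is "{network.compartments[0][1]}";')
    return "\n".join(lines) + "\n"


def tca_fixture() -> Network:
    """The TCA-cycle demonstration network (9 reactions, 20 species)."""
    return parse_model(TCA_MODEL_TEXT)


def generate_random_network(n_species: int, n_reactions: int, seed: int) -> Network:
    """Deterministic random network for tests and benchmarks.

    Each reaction draws 1-3 reactants and 1-3 products from the species pool,
    with reactant and product sets disjoint (no self-loops).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_reactions < 0:
        raise ValueError("n_reactions must be >= 0")
    if n_reactions > 0 and n_species < 2:
        raise ValueError("need at least 2 species to build self-loop-free reactions")
    rng = random.Random(seed)
    comp_id = DEFAULT_COMPARTMENT_ID
    species = [Species(f"S{i}", f"S{i}", comp_id) for i in range(1, n_species + 1)]
    ids = [s.id for s in species]
    reactions = []
    for j in range(1, n_reactions + 1):
        n_r = rng.randint(1, min(3, n_species - 1))
        n_p = rng.randint(1, min(3, n_species - n_r))
        chosen = rng.sample(ids, n_r + n_p)
        parts = [Participant(sid, "reactant") for sid in chosen[:n_r]]
        parts += [Participant(sid, "product") for sid in chosen[n_r:]]
        reactions.append(Reaction(f"R{j}", parts))
    net = Network(species, reactions, [(comp_id, comp_id)])
    net.validate()
    return net
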
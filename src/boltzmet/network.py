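"""Reaction-network model: species, reactions, stoichiometry, boundary conditions.

A :class:`ReactionNetwork` couples a list of species — each carrying a standard
chemical potential ``mu0`` (kJ/mol) and a role (``dynamic`` or ``clamped``) —
with a list of integer-stoichiometry reactions.  Potentials are reduced once,
at load time, to the dimensionless ``mu_hat = mu0 / k_B T`` (in molar units,
``mu0 / RT``); every downstream computation is dimensionless.

Clamped species are chemostatted boundary conditions: their counts are held at
``clamp_count`` by the simulator, and their chemical potentials enter reaction
likelihood ratios as driving forces.

Two equivalent on-disk dialects are supported: a single JSON document, or a
``species.tsv`` / ``reactions.tsv`` pair (tab-separated, ``#`` comments).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Molar gas constant, J mol^-1 K^-1 (CODATA 2018, exact).
GAS_CONSTANT_J = 8.31446261815324

DYNAMIC = "dynamic"
CLAMPED = "clamped"


class NetworkError(ValueError):
    """Raised for malformed network files or inconsistent network definitions."""


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and the derived thermal energy scale.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Must be positive.
    """

    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise NetworkError(f"temperature must be positive, got {self.temperature}")

    @property
    def kBT_kJ_per_mol(self) -> float:
        """Thermal energy RT in kJ/mol (≈ 2.45 kJ/mol at room temperature)."""
        return GAS_CONSTANT_J * self.temperature / 1000.0


@dataclass(frozen=True)
class Species:
    """A chemical species with a standard chemical potential.

    ``mu_hat`` is the reduced (dimensionless) potential ``mu0 / RT``; it equals
    minus the log of the molecular partition function, internal degrees of
    freedom being disregarded.
    """

    id: str
    mu0: float
    mu_hat: float
    role: str = DYNAMIC
    clamp_count: int | None = None

    def __post_init__(self) -> None:
        if self.role not in (DYNAMIC, CLAMPED):
            raise NetworkError(f"species {self.id!r}: unknown role {self.role!r}")
        if not np.isfinite(self.mu_hat):
            raise NetworkError(f"species {self.id!r}: non-finite reduced potential")
        if self.role == CLAMPED:
            if self.clamp_count is None:
                raise NetworkError(f"clamped species {self.id!r} requires clamp_count")
            if self.clamp_count < 0:
                raise NetworkError(f"species {self.id!r}: clamp_count must be >= 0")
        elif self.clamp_count is not None:
            raise NetworkError(f"dynamic species {self.id!r} must not set clamp_count")


@dataclass(frozen=True)
class Reaction:
    """An integer-stoichiometry reaction ``reactants -> products``."""

    id: str
    reactants: dict[str, int]
    products: dict[str, int]

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise NetworkError(f"reaction {self.id!r}: both sides must be non-empty")
        for side in (self.reactants, self.products):
            for sid, coef in side.items():
                if not isinstance(coef, int) or coef <= 0:
                    raise NetworkError(
                        f"reaction {self.id!r}: coefficient of {sid!r} must be a "
                        f"positive integer, got {coef!r}"
                    )
        if all(v == 0 for v in self.net_change().values()):
            raise NetworkError(f"reaction {self.id!r}: net change is zero everywhere")

    def net_change(self) -> dict[str, int]:
        """products − reactants, per species (zero entries retained)."""
        net: dict[str, int] = {}
        for sid, coef in self.reactants.items():
            net[sid] = net.get(sid, 0) - coef
        for sid, coef in self.products.items():
            net[sid] = net.get(sid, 0) + coef
        return net

    def equation(self) -> str:
        def side(terms: dict[str, int]) -> str:
            return " + ".join(
                (f"{c} {s}" if c != 1 else s) for s, c in sorted(terms.items())
            )

        return f"{side(self.reactants)} -> {side(self.products)}"


_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")
_BAD_COEF_RE = re.compile(r"^([\d.eE+-]+)\s+\S+$")


def parse_equation(equation: str) -> tuple[dict[str, int], dict[str, int]]:
    """Parse ``"a A + b B -> c C"`` into (reactants, products) coefficient maps."""
    if "->" not in equation:
        raise NetworkError(f"equation {equation!r}: missing '->' separator")
    lhs, rhs = equation.split("->", 1)

    def parse_side(side: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"equation {equation!r}: empty term")
            m = _TERM_RE.match(term)
            if m is None:
                bad = _BAD_COEF_RE.match(term)
                if bad is not None:
                    raise NetworkError(
                        f"equation {equation!r}: non-integer coefficient {bad.group(1)!r}"
                    )
                raise NetworkError(f"equation {equation!r}: cannot parse term {term!r}")
            coef = int(m.group(1)) if m.group(1) else 1
            sid = m.group(2)
            out[sid] = out.get(sid, 0) + coef
        return out

    return parse_side(lhs), parse_side(rhs)


@dataclass
class ReactionNetwork:
    """Validated container for species, reactions and the stoichiometric matrix.

    ``stoich`` has one row per species (in ``species`` order) and one column
    per reaction; column r equals products − reactants of reaction r.
    """

    context: ThermoContext
    species: list[Species]
    reactions: list[Reaction]
    stoich: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise NetworkError(f"duplicate species ids: {sorted(dup)}")
        rids = [r.id for r in self.reactions]
        dupr = {i for i in rids if rids.count(i) > 1}
        if dupr:
            raise NetworkError(f"duplicate reaction ids: {sorted(dupr)}")
        self._sidx = {s.id: i for i, s in enumerate(self.species)}
        self._ridx = {r.id: j for j, r in enumerate(self.reactions)}
        stoich = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for sid, dn in rxn.net_change().items():
                if sid not in self._sidx:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references undeclared species {sid!r}"
                    )
                stoich[self._sidx[sid], j] = dn
        self.stoich = stoich
        self.mu_hat = np.array([s.mu_hat for s in self.species])
        self.dynamic_mask = np.array([s.role == DYNAMIC for s in self.species])
        self.clamp_counts = np.array(
            [s.clamp_count if s.role == CLAMPED else 0 for s in self.species],
            dtype=np.int64,
        )

    # -- lookups -----------------------------------------------------------
    def species_index(self, sid: str) -> int:
        try:
            return self._sidx[sid]
        except KeyError:
            raise NetworkError(f"unknown species {sid!r}") from None

    def reaction_index(self, rid: str) -> int:
        try:
            return self._ridx[rid]
        except KeyError:
            raise NetworkError(f"unknown reaction {rid!r}") from None

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def dynamic_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == DYNAMIC)

    @property
    def clamped_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == CLAMPED)


def net_stoichiometry(
    net: ReactionNetwork, multiset: dict[str, int]
) -> dict[str, int]:
    """Net species change of a signed multiset of reactions.

    Returns ``Σ_r multiplicity_r × (stoichiometric column r)`` as a map from
    species id to signed integer (zero entries included).
    """
    total = np.zeros(len(net.species), dtype=np.int64)
    for rid, mult in multiset.items():
        total += mult * net.stoich[:, net.reaction_index(rid)]
    return {sid: int(total[i]) for i, sid in enumerate(net.species_ids)}


def validate_network(net: ReactionNetwork) -> list[str]:
    """Non-fatal diagnostics: unused species, reactions with no dynamic effect."""
    diags: list[str] = []
    used = np.abs(net.stoich).sum(axis=1) > 0
    referenced = {
        sid for r in net.reactions for sid in (*r.reactants, *r.products)
    }
    for i, sp in enumerate(net.species):
        if not used[i] and sp.id not in referenced:
            diags.append(f"unused species: {sp.id!r} is referenced by no reaction")
    for j, rxn in enumerate(net.reactions):
        touched = {*rxn.reactants, *rxn.products}
        if all(net.species[net.species_index(s)].role == CLAMPED for s in touched):
            diags.append(
                f"no dynamic effect: reaction {rxn.id!r} touches only clamped species"
            )
        elif not np.any(net.stoich[net.dynamic_mask, j]):
            diags.append(
                f"no dynamic effect: reaction {rxn.id!r} has zero net change on "
                f"dynamic species (pure cofactor turnover)"
            )
    return diags


# ---------------------------------------------------------------------------
# File dialect
# ---------------------------------------------------------------------------

def _species_from_record(
    rec: dict, context: ThermoContext, where: str
) -> Species:
    try:
        sid = rec["id"]
        mu0 = float(rec["mu0_kJ_per_mol"])
        role = rec.get("role", DYNAMIC)
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkError(f"{where}: malformed species record ({exc})") from None
    clamp = rec.get("clamp_count")
    if clamp is not None:
        clamp = int(clamp)
    return Species(
        id=sid,
        mu0=mu0,
        mu_hat=mu0 / context.kBT_kJ_per_mol,
        role=role,
        clamp_count=clamp,
    )


def load_network(path: str | Path, context: ThermoContext | None = None) -> ReactionNetwork:
    """Load a network from the JSON dialect or a TSV-pair directory.

    ``path`` is either a ``.json`` file or a directory containing
    ``species.tsv`` and ``reactions.tsv``.  If ``context`` is given it
    overrides the temperature recorded in the file.
    """
    path = Path(path)
    if path.is_dir():
        return _load_tsv(path, context)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise NetworkError(f"{path}: JSON parse error at line {exc.lineno}") from None
    ctx = context or ThermoContext(float(doc.get("temperature_K", 298.15)))
    species = [
        _species_from_record(rec, ctx, f"{path}: species[{i}]")
        for i, rec in enumerate(doc.get("species", []))
    ]
    reactions = []
    for i, rec in enumerate(doc.get("reactions", [])):
        try:
            rid, eq = rec["id"], rec["equation"]
        except (KeyError, TypeError):
            raise NetworkError(f"{path}: reactions[{i}]: missing id/equation") from None
        reactants, products = parse_equation(eq)
        reactions.append(Reaction(id=rid, reactants=reactants, products=products))
    return ReactionNetwork(context=ctx, species=species, reactions=reactions)


def _read_tsv(path: Path) -> tuple[list[list[str]], dict[str, str]]:
    """Rows (tab-split, comments stripped) and ``# key: value`` header metadata."""
    rows: list[list[str]] = []
    meta: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not line.strip():
            continue
        rows.append([c.strip() for c in line.split("\t")] + [str(lineno)])
    return rows, meta


def _load_tsv(directory: Path, context: ThermoContext | None) -> ReactionNetwork:
    sp_path = directory / "species.tsv"
    rx_path = directory / "reactions.tsv"
    for p in (sp_path, rx_path):
        if not p.exists():
            raise NetworkError(f"missing network file: {p}")
    sp_rows, meta = _read_tsv(sp_path)
    ctx = context or ThermoContext(float(meta.get("temperature_K", 298.15)))
    species = []
    header_skipped = False
    for row in sp_rows:
        *cells, lineno = row
        if not header_skipped and cells[0] == "id":
            header_skipped = True
            continue
        if len(cells) < 3:
            raise NetworkError(f"{sp_path}:{lineno}: expected >=3 columns")
        rec: dict = {"id": cells[0], "mu0_kJ_per_mol": cells[1], "role": cells[2]}
        if len(cells) > 3 and cells[3] != "":
            rec["clamp_count"] = cells[3]
        species.append(_species_from_record(rec, ctx, f"{sp_path}:{lineno}"))
    reactions = []
    header_skipped = False
    for row in _read_tsv(rx_path)[0]:
        *cells, lineno = row
        if not header_skipped and cells[0] == "id":
            header_skipped = True
            continue
        if len(cells) < 2:
            raise NetworkError(f"{rx_path}:{lineno}: expected 2 columns (id, equation)")
        reactants, products = parse_equation(cells[1])
        reactions.append(Reaction(id=cells[0], reactants=reactants, products=products))
    return ReactionNetwork(context=ctx, species=species, reactions=reactions)


def write_network(
    net: ReactionNetwork,
    path: str | Path,
    fmt: str = "json",
    header_comments: list[str] | None = None,
) -> None:
    """Write a network in the JSON dialect (``fmt='json'``, a file path) or as
    a ``species.tsv``/``reactions.tsv`` pair (``fmt='tsv'``, a directory)."""
    path = Path(path)
    if fmt == "json":
        doc = {
            "temperature_K": net.context.temperature,
            "species": [
                {
                    "id": s.id,
                    "mu0_kJ_per_mol": s.mu0,
                    "role": s.role,
                    **({"clamp_count": s.clamp_count} if s.role == CLAMPED else {}),
                }
                for s in net.species
            ],
            "reactions": [
                {"id": r.id, "equation": r.equation()} for r in net.reactions
            ],
        }
        if header_comments:
            doc["comments"] = list(header_comments)
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        head = [f"# {c}" for c in (header_comments or [])]
        head.append(f"# temperature_K: {net.context.temperature!r}")
        sp_lines = head + ["id\tmu0_kJ_per_mol\trole\tclamp_count"]
        for s in net.species:
            clamp = "" if s.clamp_count is None else str(s.clamp_count)
            sp_lines.append(f"{s.id}\t{s.mu0!r}\t{s.role}\t{clamp}")
        (path / "species.tsv").write_text("\n".join(sp_lines) + "\n")
        rx_lines = head + ["id\tequation"]
        for r in net.reactions:
            rx_lines.append(f"{r.id}\t{r.equation()}")
        (path / "reactions.tsv").write_text("\n".join(rx_lines) + "\n")
    else:
        raise NetworkError(f"unknown network format {fmt!r}")
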
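"""Model definition, file dialect, and output writers.

A model consists of molecule-type definitions (rigid arrangements of named
interface sites around a center of mass, plus translational/rotational
diffusion constants), reaction rules in a rule-based site/bond syntax
(``A(c) + A(q) <-> A(c!1).A(q!1)``), and a simulation configuration (box,
timestep, iterations, seed, initial copy numbers).

The dialect is deliberately independent and versioned:

* configuration: YAML key/value (``box``, ``dt``, ``n_iterations``, ``seed``,
  ``copies``, ``membrane``, ...);
* molecule files: plain-text blocks (``name``, ``D``, ``Drot``, ``site``
  lines, optional ``2D`` / ``implicit_surface`` flags);
* reaction files: blocks starting with a ``reaction`` pattern line followed
  by rate/geometry keys (``kon``/``koff`` macroscopic or ``ka``/``kb``
  intrinsic, ``sigma``, ``h``, ``dG_coop``, ``loop_closure``, ``angles``).

Units in files are the field's display units (uM^-1 s^-1, s^-1, nm, um^2/s,
rad^2/us); everything is converted to internal nm/us units at parse time.

Outputs: TSV time series (copy numbers and uM concentrations), appendable
XYZ snapshots (one record per site and center of mass), JSON restart state.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import yaml

from . import rate_theory
from ._units import (copies_to_uM, kon3d_to_display, kon3d_to_internal,
                     rate1_to_display, rate1_to_internal)

DIALECT_VERSION = 1


class ModelParseError(ValueError):
    """Syntax or reference error in a model file; message names file/line."""


# --------------------------------------------------------------------------
# domain types

@dataclass
class MoleculeType:
    """Species template: rigid site geometry plus transport coefficients."""
    name: str
    site_names: list
    site_offsets: np.ndarray        # (n_sites, 3) nm, relative to COM
    Dt: np.ndarray                  # (3,) nm^2/us per axis
    Drot: float                     # rad^2/us
    is_2d: bool = False
    is_implicit_surface: bool = False
    type_id: int = -1

    def __post_init__(self):
        self.site_offsets = np.asarray(self.site_offsets, dtype=np.float64
                                       ).reshape(len(self.site_names), 3)
        self.Dt = np.asarray(self.Dt, dtype=np.float64).reshape(3)
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.site_offsets)):
            raise ModelParseError(f"{self.name}: non-finite site offset")
        if np.any(self.Dt < 0):
            raise ModelParseError(f"{self.name}: negative diffusion constant")
        if self.is_2d and self.Dt[2] != 0.0:
            raise ModelParseError(f"{self.name}: a 2D species must have Dt_z = 0")
        if len(set(self.site_names)) != len(self.site_names):
            raise ModelParseError(f"{self.name}: duplicate site names")

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    def site_index(self, name: str) -> int:
        try:
            return self.site_names.index(name)
        except ValueError:
            raise ModelParseError(f"unknown site {name!r} on {self.name}") from None

    def sites_matching(self, pattern: str) -> list:
        """Site indices matching an exact name or a ``prefix*`` wildcard
        (symmetric sites such as the three legs of a triskelion)."""
        if pattern.endswith("*"):
            pre = pattern[:-1]
            out = [i for i, nm in enumerate(self.site_names)
                   if nm.startswith(pre)]
            if not out:
                raise ModelParseError(
                    f"no site matches {pattern!r} on {self.name}")
            return out
        return [self.site_index(pattern)]

    @property
    def max_site_extent(self) -> float:
        if self.n_sites == 0:
            return 0.0
        return float(np.max(np.linalg.norm(self.site_offsets, axis=1)))

    @property
    def D_mean(self) -> float:
        """Per-axis mean translational diffusion (the D entering pair formulas)."""
        return float(np.mean(self.Dt))


@dataclass
class SitePattern:
    """One reactant of a rule: a molecule type, the reacting site, and any
    context conditions on *other* sites ('bound' / 'free')."""
    mol: str
    site: str
    context: list = field(default_factory=list)  # (site_name, 'bound'|'free')


@dataclass
class ReactionRule:
    """0th/1st/2nd-order reaction rule with intrinsic and macroscopic rates.

    Rates are stored in internal units (nm^3/us, nm^2/us, us^-1); sigma, h
    in nm; dG_coop in kBT.  Partially specified rules are completed by
    :func:`prd.rate_theory.complete_rates` once molecule types are known.
    """
    name: str
    order: int
    reactants: list                       # SitePattern list (order-2: two)
    reversible: bool = True
    text: str = ""
    # rates (exactly one of macro / intrinsic supplied for order 2)
    kon_macro: float | None = None        # nm^3/us (3D) or nm^2/us (2D)
    koff_macro: float | None = None       # us^-1
    ka_intrinsic: float | None = None
    kb_intrinsic: float | None = None
    k_macro: float | None = None          # order 0/1 rate
    k_intrinsic: float | None = None
    # geometry
    sigma: float = 0.0
    h: float | None = None                # 3D->2D conversion length, nm
    dG_coop: float = 0.0                  # kBT
    angles: tuple | None = None           # (theta1, theta2, phi1, phi2, omega)
    norm1: tuple | None = None
    norm2: tuple | None = None
    is_loop_closure_eligible: bool = False
    implicit_surface: bool = False        # partner is a density-field species
    # derived (filled during completion)
    dimensionality: int = 3
    projects_to_2d: bool = False
    D_pair: float = 0.0
    l1: float = 0.0
    l2: float = 0.0
    b_rho: float | None = None
    ka2d_intrinsic: float | None = None
    kb2d_intrinsic: float | None = None
    kclose: float | None = None
    rule_id: int = -1
    lipid_type_id: int = -1           # implicit-surface partner's type id
    binder_index: int = 0             # which reactant is the explicit binder

    def validate(self) -> None:
        if self.order == 2 and not self.sigma > 0:
            raise ModelParseError(f"rule {self.name}: order-2 rule requires sigma > 0")

    @property
    def ka_for_dim(self) -> float:
        """Intrinsic forward rate in the rule's native dimensionality."""
        if self.dimensionality == 2 and not self.projects_to_2d:
            return self.ka_intrinsic
        return self.ka_intrinsic


@dataclass
class SimulationConfig:
    """Run geometry, stepping and bookkeeping parameters (internal units)."""
    box: np.ndarray                 # (3,) nm
    dt: float                       # us
    n_iterations: int
    seed: int = 0
    output_every: int = 100
    ranks: int = 1
    transport: str = "loopback"     # or "mpi"
    membrane: bool = False          # reflecting surface with 2D species at z=0
    copies: dict = field(default_factory=dict)       # type name -> initial N
    implicit_lipid_copies: int = 0

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if np.any(self.box <= 0):
            raise ModelParseError("box lengths must be positive")
        if self.dt <= 0:
            raise ModelParseError("dt must be positive")
        if self.transport not in ("loopback", "mpi"):
            raise ModelParseError(f"unknown transport {self.transport!r}")

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def area(self) -> float:
        return float(self.box[0] * self.box[1])


@dataclass
class Model:
    """Parsed model: types, completed rules, configuration."""
    types: dict                     # name -> MoleculeType
    rules: list                     # ReactionRule
    config: SimulationConfig

    @property
    def type_list(self) -> list:
        return sorted(self.types.values(), key=lambda t: t.type_id)


# --------------------------------------------------------------------------
# pattern / rule-text parsing

_PAT_RE = re.compile(r"^\s*(\w+)\s*(?:\(\s*([^)]*)\s*\))?\s*$")


def _split_top(text: str, sep: str) -> list:
    """Split on ``sep`` outside parentheses (``!+`` lives inside them)."""
    out, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return [t.strip() for t in out if t.strip()]


def _parse_component(tok: str, where: str) -> tuple:
    """One molecule component -> (mol, reacting site or None, context)."""
    m = _PAT_RE.match(tok)
    if not m:
        raise ModelParseError(f"{where}: cannot parse pattern {tok!r}")
    mol, sites = m.group(1), m.group(2)
    react_site = None
    context = []
    for p in [s.strip() for s in (sites or "").split(",") if s.strip()]:
        if "!" in p:                     # bound site (!+ or !n): context
            context.append((p.split("!")[0], "bound"))
        elif react_site is None:
            react_site = p               # first free site reacts
        else:
            context.append((p, "free"))
    return mol, react_site, context


def _parse_pattern(tok: str, where: str) -> SitePattern:
    """A reactant: possibly a dotted bound-complex pattern; the component
    carrying an unbound site is the reacting molecule, its bound sites (and
    the other components) become context conditions."""
    comps = [_parse_component(c, where) for c in _split_top(tok, ".")]
    for mol, site, ctx in comps:
        if site is not None:
            return SitePattern(mol, site, ctx)
    mol, _, ctx = comps[0]
    return SitePattern(mol, "", ctx)


def parse_rule_text(text: str, where: str = "<rule>") -> tuple:
    """Parse a rule pattern line.

    Returns (order, reactants, reversible, kind) where kind is one of
    'binding', 'creation', 'decay'.
    """
    text = text.strip()
    reversible = "<->" in text
    lhs, _, _rhs = text.partition("<->" if reversible else "->")
    lhs = lhs.strip()
    if lhs == "0":                      # 0 -> A
        prod = _parse_pattern(_rhs.strip().split(".")[0], where)
        return 0, [prod], False, "creation"
    pats = [_parse_pattern(t, where) for t in _split_top(lhs, "+")]
    if _rhs.strip() == "0":
        return 1, pats, False, "decay"
    if len(pats) == 2:
        return 2, pats, reversible, "binding"
    raise ModelParseError(f"{where}: unsupported rule form {text!r}")


# --------------------------------------------------------------------------
# file parsing

def parse_molecule_file(path) -> MoleculeType:
    """Parse one molecule-type block file."""
    path = Path(path)
    name = None
    Dt = None
    Drot = 0.0
    is2d = False
    implicit = False
    site_names, offsets = [], []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, *rest = line.split()
        where = f"{path.name}:{ln}"
        try:
            if key == "name":
                name = rest[0]
            elif key == "D":
                Dt = [float(x) for x in rest[:3]]      # um^2/s == nm^2/us
            elif key == "Drot":
                Drot = float(rest[0])
            elif key == "2D":
                is2d = True
            elif key == "implicit_surface":
                implicit = True
            elif key == "site":
                site_names.append(rest[0])
                offsets.append([float(x) for x in rest[1:4]])
            else:
                raise ModelParseError(f"{where}: unknown key {key!r}")
        except (IndexError, ValueError) as e:
            raise ModelParseError(f"{where}: {e}") from None
    if name is None or Dt is None:
        raise ModelParseError(f"{path.name}: molecule file needs 'name' and 'D'")
    if is2d:
        Dt[2] = 0.0
    return MoleculeType(name, site_names, np.array(offsets, dtype=float).reshape(-1, 3),
                        Dt, Drot, is_2d=is2d, is_implicit_surface=implicit)


_RATE_KEYS = {
    "kon": ("kon_macro", "macro"), "koff": ("koff_macro", "macro"),
    "ka": ("ka_intrinsic", "intr"), "kb": ("kb_intrinsic", "intr"),
    "ka2d": ("ka_intrinsic", "intr"), "kb2d": ("kb_intrinsic", "intr"),
    "k": ("k_macro", "macro"),
}


def parse_reaction_file(path) -> list:
    """Parse a reaction file into (uncompleted) ReactionRule objects."""
    path = Path(path)
    rules: list[ReactionRule] = []
    cur: ReactionRule | None = None
    macro_seen: set = set()
    intr_seen: set = set()
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        where = f"{path.name}:{ln}"
        if not line:
            continue
        key, _, rest = line.partition(" ")
        rest = rest.strip()
        if key == "reaction":
            order, pats, rev, kind = parse_rule_text(rest, where)
            cur = ReactionRule(name=f"r{len(rules)}", order=order,
                               reactants=pats, reversible=rev, text=rest)
            rules.append(cur)
            continue
        if cur is None:
            raise ModelParseError(f"{where}: key before any 'reaction' line")
        try:
            if key in _RATE_KEYS:
                attr, fam = _RATE_KEYS[key]
                setattr(cur, attr, float(rest))
                (macro_seen if fam == "macro" else intr_seen).add(cur.name)
                if key in ("ka2d", "kb2d"):
                    cur.dimensionality = 2
            elif key == "sigma":
                cur.sigma = float(rest)
            elif key == "h":
                cur.h = float(rest)
            elif key == "dG_coop":
                cur.dG_coop = float(rest)
            elif key == "loop_closure":
                cur.is_loop_closure_eligible = rest.lower() in ("on", "true", "1")
            elif key == "angles":
                cur.angles = tuple(float(x) for x in rest.split())
            elif key == "name":
                cur.name = rest
            else:
                raise ModelParseError(f"{where}: unknown key {key!r}")
        except ValueError as e:
            raise ModelParseError(f"{where}: {e}") from None
    for r in rules:
        if r.name in macro_seen and r.name in intr_seen:
            raise ModelParseError(
                f"{path.name}: rule {r.name} ({r.text}): both macroscopic and "
                "intrinsic rates given")
    return rules


def parse_config_file(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> SimulationConfig:
    return SimulationConfig(
        box=data["box"],
        dt=float(data["dt"]),
        n_iterations=int(data.get("n_iterations", 0)),
        seed=int(data.get("seed", 0)),
        output_every=int(data.get("output_every", 100)),
        ranks=int(data.get("ranks", 1)),
        transport=data.get("transport", "loopback"),
        membrane=bool(data.get("membrane", False)),
        copies={str(k): int(v) for k, v in (data.get("copies") or {}).items()},
        implicit_lipid_copies=int(data.get("implicit_lipid_copies", 0)),
    )


def _complete_rules(types: dict, rules: Sequence[ReactionRule],
                    config: SimulationConfig) -> None:
    """Resolve references, fill derived rate/geometry members, validate."""
    for i, r in enumerate(rules):
        r.rule_id = i
        if r.order != 2:
            # convert display rate (s^-1, or copies/(nm^3 us) for creation)
            if r.k_macro is not None and r.order == 1:
                r.k_macro = rate1_to_internal(r.k_macro)
            rate_theory.complete_rates(r)
            continue
        r.validate()
        ta, tb = (types.get(p.mol) for p in r.reactants)
        for p in r.reactants:
            if p.mol not in types:
                raise ModelParseError(f"rule {r.name}: unknown molecule {p.mol!r}")
            t = types[p.mol]
            if p.site:
                t.sites_matching(p.site)
            for cs, _ in p.context:
                t.sites_matching(cs)
        r.implicit_surface = ta.is_implicit_surface or tb.is_implicit_surface
        if r.implicit_surface:
            r.binder_index = 1 if ta.is_implicit_surface else 0
            lip = ta if ta.is_implicit_surface else tb
            r.lipid_type_id = lip.type_id
        both_2d = ta.is_2d and tb.is_2d
        r.dimensionality = 2 if both_2d else 3
        if both_2d:
            # pure-2D pair: in-plane mean (the z component is identically 0)
            r.D_pair = float(ta.Dt[:2].mean() + tb.Dt[:2].mean())
        else:
            r.D_pair = ta.D_mean + tb.D_mean
        ia = ta.sites_matching(r.reactants[0].site) if r.reactants[0].site else []
        ib = tb.sites_matching(r.reactants[1].site) if r.reactants[1].site else []
        r.l1 = float(max(np.linalg.norm(ta.site_offsets[i]) for i in ia)) if ia else 0.0
        r.l2 = float(max(np.linalg.norm(tb.site_offsets[i]) for i in ib)) if ib else 0.0
        r.projects_to_2d = (r.h is not None) and not both_2d
        # convert display units -> internal
        if r.kon_macro is not None and r.dimensionality == 3:
            r.kon_macro = kon3d_to_internal(r.kon_macro)
        if r.koff_macro is not None:
            r.koff_macro = rate1_to_internal(r.koff_macro)
        if r.kb_intrinsic is not None:
            r.kb_intrinsic = rate1_to_internal(r.kb_intrinsic)
        if r.dimensionality == 2:
            na = config.copies.get(ta.name, 0)
            nb = config.copies.get(tb.name, 0)
            n_max = max(na, nb, 1)
            r.b_rho = rate_theory.b_rho_2d(config.area, n_max, r.sigma)
        rate_theory.complete_rates(r)
        if (both_2d or r.implicit_surface or ta.is_2d or tb.is_2d) \
                and not config.membrane:
            raise ModelParseError(
                f"rule {r.name}: membrane flag must be set for 2D / surface rules")


def parse_model(molecule_paths: Iterable, reaction_path, config_path) -> Model:
    """Parse and cross-validate a complete model from its files."""
    config = parse_config_file(config_path)
    types = {}
    for p in molecule_paths:
        t = parse_molecule_file(p)
        t.type_id = len(types)
        types[t.name] = t
    rules = parse_reaction_file(reaction_path) if reaction_path else []
    _complete_rules(types, rules, config)
    return Model(types, rules, config)


def model_from_objects(types: dict, rules: list, config: SimulationConfig) -> Model:
    """Build a Model from in-memory objects (benchmark builders use this)."""
    for i, t in enumerate(types.values()):
        t.type_id = i
    _complete_rules(types, rules, config)
    return Model(types, rules, config)


# --------------------------------------------------------------------------
# writers

def write_molecule_file(t: MoleculeType, fh: IO) -> None:
    fh.write(f"name {t.name}\n")
    fh.write("D " + " ".join(f"{x:.17g}" for x in t.Dt) + "\n")
    fh.write(f"Drot {t.Drot:.17g}\n")
    if t.is_2d:
        fh.write("2D\n")
    if t.is_implicit_surface:
        fh.write("implicit_surface\n")
    for nm, off in zip(t.site_names, t.site_offsets):
        fh.write(f"site {nm} " + " ".join(f"{x:.17g}" for x in off) + "\n")


def write_reaction_file(rules: Sequence[ReactionRule], fh: IO) -> None:
    """Write rules in display units (inverse of the parse-time conversion)."""
    for r in rules:
        fh.write(f"reaction {r.text}\n")
        fh.write(f"name {r.name}\n")
        if r.order == 2:
            if r.dimensionality == 2:
                fh.write(f"ka2d {r.ka_intrinsic:.17g}\n")
                if r.kb_intrinsic is not None:
                    fh.write(f"kb2d {rate1_to_display(r.kb_intrinsic):.17g}\n")
            else:
                fh.write(f"kon {kon3d_to_display(r.kon_macro):.17g}\n")
                if r.koff_macro is not None:
                    fh.write(f"koff {rate1_to_display(r.koff_macro):.17g}\n")
            fh.write(f"sigma {r.sigma:.17g}\n")
            if r.h is not None:
                fh.write(f"h {r.h:.17g}\n")
            if r.dG_coop:
                fh.write(f"dG_coop {r.dG_coop:.17g}\n")
            if r.is_loop_closure_eligible:
                fh.write("loop_closure on\n")
            if r.angles is not None:
                fh.write("angles " + " ".join(f"{a:.17g}" for a in r.angles) + "\n")
        elif r.k_macro is not None:
            k = rate1_to_display(r.k_macro) if r.order == 1 else r.k_macro
            fh.write(f"k {k:.17g}\n")
        fh.write("\n")


def write_config_file(config: SimulationConfig, fh: IO) -> None:
    data = {
        "box": [float(x) for x in config.box],
        "dt": config.dt,
        "n_iterations": config.n_iterations,
        "seed": config.seed,
        "output_every": config.output_every,
        "ranks": config.ranks,
        "transport": config.transport,
        "membrane": config.membrane,
        "copies": dict(config.copies),
        "implicit_lipid_copies": config.implicit_lipid_copies,
    }
    yaml.safe_dump(data, fh, sort_keys=False)


def write_model(model: Model, outdir) -> dict:
    """Write a model to a directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mol_paths = []
    for t in model.type_list:
        p = outdir / f"{t.name}.mol"
        with open(p, "w") as fh:
            write_molecule_file(t, fh)
        mol_paths.append(p)
    rxn = outdir / "reactions.txt"
    with open(rxn, "w") as fh:
        write_reaction_file(model.rules, fh)
    cfg = outdir / "config.yml"
    with open(cfg, "w") as fh:
        write_config_file(model.config, fh)
    return {"molecules": mol_paths, "reactions": rxn, "config": cfg}


def write_timeseries(records: Sequence[dict], fh: IO, volume_nm3: float) -> None:
    """Tab-separated time series: time, then per-species copy number and uM.

    ``records`` is a list of {"time": t_us, "counts": {species: N}} sharing
    one schema; concentrations are N / (NA * V).
    """
    if not records:
        return
    species = list(records[0]["counts"].keys())
    header = ["time_us"]
    for s in species:
        header += [f"{s}_N", f"{s}_uM"]
    fh.write("\t".join(header) + "\n")
    for rec in records:
        row = [f"{rec['time']:.10g}"]
        for s in species:
            n = rec["counts"][s]
            row += [str(int(n)), f"{copies_to_uM(n, volume_nm3):.10g}"]
        fh.write("\t".join(row) + "\n")


def write_snapshot(state, t: float, fh: IO) -> None:
    """Append one XYZ frame: a record per center of mass and per site."""
    labels, coords = state.snapshot_records()
    fh.write(f"{len(labels)}\n")
    fh.write(f"t= {t:.10g} us\n")
    for lab, xyz in zip(labels, coords):
        fh.write(f"{lab} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def write_restart(state, path) -> None:
    """JSON restart state (molecule table, bonds, complexes, rng step)."""
    Path(path).write_text(json.dumps(state.to_dict(), indent=None))
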
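"""Signaling-network topology: species, edges, conservation pairs.

The molecular model is generated from a :class:`SignalingNetwork`, a fixed
reaction topology in which every tracked state variable is the phosphorylated
(or receptor-complexed) form of a protein and the unphosphorylated complement
is recovered algebraically from a conserved total.  The canonical network
wires the two osteogenic ligands, BMP-2 and IGF-1, through their receptor
complexes into the TAK1/p38-SMAD1/5, Ras/Raf/MEK/ERK and PI3K/PDK1/Akt/mTOR
cascades, terminating on four transcription-factor outputs (Runx2, osterix,
beta-catenin and a proliferative TF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

ACTIVATE = "activate"
INHIBIT = "inhibit"

#: species kinds
DYNAMIC = "dynamic"      # has an ODE
ALGEBRAIC = "algebraic"  # computed from a conservation pair
INPUT = "input"          # externally prescribed (ligands, constant pools)

N_DYNAMIC = 20
N_ALGEBRAIC = 16
N_VARIABLES = N_DYNAMIC + N_ALGEBRAIC
N_PARAMETERS = 37


@dataclass(frozen=True)
class Edge:
    """Directed interaction between two species.

    ``source_form`` selects which pool of the source acts: the phosphorylated
    form (default) or its unphosphorylated complement.  The complement form is
    needed for GSK3beta -> beta-catenin, where the *unphosphorylated* kinase is
    the active one.  ``weight`` is a fixed structural multiplier (crosstalk
    edges may be weaker than trunk edges); it is part of the topology, not a
    fitted rate.
    """

    source: str
    target: str
    sign: str = ACTIVATE
    weight: float = 1.0
    source_form: str = "phospho"


@dataclass
class SignalingNetwork:
    species: dict[str, str]                      # name -> kind
    edges: list[Edge]
    pairs: list[tuple[str, str, str]]            # (phospho, base, total_id)
    ligand_bindings: list[tuple[str, str, str]]  # (ligand, receptor, complex)
    totals: dict[str, float] = field(default_factory=dict)

    # -- views ------------------------------------------------------------
    def dynamic_species(self) -> list[str]:
        return [s for s, k in self.species.items() if k == DYNAMIC]

    def algebraic_species(self) -> list[str]:
        return [s for s, k in self.species.items() if k == ALGEBRAIC]

    def input_species(self) -> list[str]:
        return [s for s, k in self.species.items() if k == INPUT]

    def paired_dynamic(self) -> list[str]:
        return [p for p, _, _ in self.pairs]

    def total_of(self, species: str) -> float:
        """Conserved total C_M of a dynamic species."""
        return self.totals[f"C_{species}"]

    def tf_species(self) -> list[str]:
        """Transcription-factor outputs: dynamic sinks of the activation graph."""
        has_out = {e.source for e in self.edges if e.sign == ACTIVATE}
        return [s for s in self.dynamic_species() if s not in has_out]

    def upstream_of(self, species: str) -> list[Edge]:
        return [e for e in self.edges if e.target == species and e.sign == ACTIVATE]

    def inhibitors_of(self, species: str) -> list[Edge]:
        return [e for e in self.edges if e.target == species and e.sign == INHIBIT]


def kinetic_parameter_ids(net: SignalingNetwork) -> list[str]:
    """Parameter ids the mass-action model of ``net`` requires.

    Conservation-paired dynamic species (phospho proteins and ligand-receptor
    complexes) each carry an activation/association rate ``a_<name>`` and a
    deactivation/dissociation rate ``d_<name>``.  Unpaired dynamic species
    (the TF outputs) carry only ``a_<name>`` and share the single decay rate
    ``d_TF`` -- the one parameter beyond the a/d pairs.
    """
    paired = set(net.paired_dynamic())
    ids: list[str] = []
    for s in net.dynamic_species():
        ids.append(f"a_{s}")
        if s in paired:
            ids.append(f"d_{s}")
    unpaired = [s for s in net.dynamic_species() if s not in paired]
    if unpaired:
        ids.append("d_TF")
    return ids


# ---------------------------------------------------------------------------
# canonical topology
# ---------------------------------------------------------------------------

#: phospho proteins tracked with an explicit conservation pair
_PAIRED_PROTEINS = [
    "TAK1", "p38", "SMAD15", "Ras", "cRaf", "MEK", "ERK",
    "PI3K", "PDK1", "Akt", "GSK3b", "mTOR", "p70S6K", "S6",
]
#: TF outputs (dynamic, unpaired; totals still conserved internally)
_TF_PROTEINS = ["Runx2", "Osterix", "bCatenin", "ProlifTF"]

_CASCADE_EDGES = [
    # BMP-2 arm
    ("BMP2_R", "TAK1"),
    ("TAK1", "p38"),
    ("p38", "Runx2"),
    ("BMP2_R", "SMAD15"),
    ("SMAD15", "Runx2"),
    # IGF-1 / MAPK arm
    ("IGF1_R", "Ras"),
    ("Ras", "cRaf"),
    ("cRaf", "MEK"),
    ("MEK", "ERK"),
    ("ERK", "ProlifTF"),
    # IGF-1 / PI3K arm
    ("IGF1_R", "PI3K"),
    ("PI3K", "PDK1"),
    ("PDK1", "Akt"),
    ("Akt", "GSK3b"),
    ("Akt", "mTOR"),
    ("mTOR", "p70S6K"),
    ("p70S6K", "S6"),
    ("mTOR", "Osterix"),
    ("S6", "ProlifTF"),
]


def build_canonical_network() -> SignalingNetwork:
    """Canonical BMP-2/IGF-1 osteogenic signaling topology.

    20 dynamic species (14 paired phospho proteins, 2 ligand-receptor
    complexes, 4 TF outputs), 16 algebraic complements, 36 variables and a
    37-rate parameterization.  Deterministic: repeated calls build identical
    structures.

    Sign conventions
    ----------------
    * ERK inhibits SMAD1/5 (the ERK ⊣ SMAD crosstalk): an ``inhibit`` edge --
      phospho-ERK drives SMAD1/5 *de*phosphorylation.
    * Akt phosphorylates GSK3beta and GSK3beta phosphorylates beta-catenin;
      both phosphorylated pools are the degraded/inactive ones, so the
      GSK3b -> bCatenin edge acts through the *unphosphorylated* GSK3beta
      pool (``source_form="unphospho"``).
    * A weak BMP2-complex -> PI3K crosstalk edge (weight 0.4) lets prior BMP-2
      exposure potentiate the Akt axis.
    """
    species: dict[str, str] = {"BMP2": INPUT, "IGF1": INPUT}
    species["BMP2_R"] = DYNAMIC
    species["IGF1_R"] = DYNAMIC
    for p in _PAIRED_PROTEINS:
        species[p] = DYNAMIC
        species[f"{p}_u"] = ALGEBRAIC
    for p in _TF_PROTEINS:
        species[p] = DYNAMIC
    species["BMPR_free"] = ALGEBRAIC
    species["IGFR_free"] = ALGEBRAIC

    edges = [Edge("BMP2", "BMP2_R"), Edge("IGF1", "IGF1_R")]
    for src, tgt in _CASCADE_EDGES:
        edges.append(Edge(src, tgt))
    edges.append(Edge("BMP2_R", "PI3K", weight=0.4))          # crosstalk
    edges.append(Edge("GSK3b", "bCatenin", source_form="unphospho"))
    edges.append(Edge("ERK", "SMAD15", sign=INHIBIT))

    pairs = [("BMP2_R", "BMPR_free", "C_BMP2_R"),
             ("IGF1_R", "IGFR_free", "C_IGF1_R")]
    pairs += [(p, f"{p}_u", f"C_{p}") for p in _PAIRED_PROTEINS]

    ligand_bindings = [("BMP2", "BMPR_free", "BMP2_R"),
                       ("IGF1", "IGFR_free", "IGF1_R")]

    totals = {f"C_{s}": 1.0 for s in _PAIRED_PROTEINS + _TF_PROTEINS}
    totals["C_BMP2_R"] = 1.0
    totals["C_IGF1_R"] = 1.0

    return SignalingNetwork(species, edges, pairs, ligand_bindings, totals)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(net: SignalingNetwork) -> list[str]:
    """Check structural invariants; returns violation messages (empty = valid)."""
    msgs: list[str] = []
    dyn, alg = net.dynamic_species(), net.algebraic_species()
    if len(dyn) != N_DYNAMIC:
        msgs.append(f"expected {N_DYNAMIC} dynamic species, found {len(dyn)}")
    if len(alg) != N_ALGEBRAIC:
        msgs.append(f"expected {N_ALGEBRAIC} algebraic species, found {len(alg)}")
    if len(dyn) + len(alg) != N_VARIABLES:
        msgs.append(
            f"expected {N_VARIABLES} variables, found {len(dyn) + len(alg)}")
    n_par = len(kinetic_parameter_ids(net))
    if n_par != N_PARAMETERS:
        msgs.append(f"expected {N_PARAMETERS} kinetic parameters, found {n_par}")

    pair_count: dict[str, int] = {}
    for ph, base, total_id in net.pairs:
        pair_count[base] = pair_count.get(base, 0) + 1
        for name in (ph, base):
            if name not in net.species:
                msgs.append(f"pair references unknown species {name!r}")
        if net.species.get(ph) != DYNAMIC:
            msgs.append(f"pair phospho member {ph!r} is not dynamic")
        if net.species.get(base) != ALGEBRAIC:
            msgs.append(f"pair base member {base!r} is not algebraic")
        if net.totals.get(total_id, 0.0) <= 0.0:
            msgs.append(f"total {total_id!r} missing or non-positive")
    for s in alg:
        n = pair_count.get(s, 0)
        if n != 1:
            msgs.append(
                f"algebraic species {s!r} appears in {n} conservation pairs "
                "(expected exactly 1)")

    for e in net.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in net.species:
                msgs.append(f"edge {e.source}->{e.target} references unknown "
                            f"species {endpoint!r}")
        if e.sign not in (ACTIVATE, INHIBIT):
            msgs.append(f"edge {e.source}->{e.target} has invalid sign {e.sign!r}")

    for ligand in ("BMP2", "IGF1"):
        if net.species.get(ligand) != INPUT:
            msgs.append(f"ligand {ligand!r} missing from species as an input")
        elif not any(e.source == ligand for e in net.edges):
            msgs.append(f"ligand {ligand!r} has no outgoing edge")

    for s in dyn:
        if net.totals.get(f"C_{s}", 0.0) <= 0.0:
            msgs.append(f"dynamic species {s!r} lacks a positive total C_{s}")
    return msgs


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def network_to_json(net: SignalingNetwork) -> str:
    payload = {
        "species": net.species,
        "edges": [asdict(e) for e in net.edges],
        "pairs": [list(p) for p in net.pairs],
        "ligand_bindings": [list(b) for b in net.ligand_bindings],
        "totals": net.totals,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def network_from_json(text: str) -> SignalingNetwork:
    payload = json.loads(text)
    return SignalingNetwork(
        species=dict(payload["species"]),
        edges=[Edge(**e) for e in payload["edges"]],
        pairs=[tuple(p) for p in payload["pairs"]],
        ligand_bindings=[tuple(b) for b in payload["ligand_bindings"]],
        totals={k: float(v) for k, v in payload["totals"].items()},
    )


def save_network(net: SignalingNetwork, path: str | Path) -> None:
    Path(path).write_text(network_to_json(net))


def load_network(path: str | Path) -> SignalingNetwork:
    return network_from_json(Path(path).read_text())
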
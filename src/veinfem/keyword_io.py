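"""Solver keyword-deck writer and re-reader.

Writes the explicit-solver input deck for meshes produced by
:mod:`veinfem.hexmesh` and :mod:`veinfem.veins` in a comma-separated
(free-format) keyword dialect: ``*NODE``, ``*ELEMENT_SOLID``,
``*ELEMENT_SHELL``, ``*ELEMENT_BEAM``, ``*SECTION_BEAM`` (annular,
encoded as a tube with outer/inner diameters d and d - 2h),
``*MAT_ELASTIC``, ``*PART`` and ``*CONSTRAINED_BEAM_IN_SOLID`` coupling
the vein beam part to the brain solids.  The reader inverts the writer
on this subset so decks can be round-tripped; unknown cards are
preserved verbatim.

Unit system: mm - ms - g (stress in MPa), stated in the deck header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hexmesh import HexMesh, Material
from .veins import BeamMesh, BeamSection

__all__ = ["KeywordDeck", "write_keyword", "read_keyword"]

_HEADER = "$ veinfem keyword deck; units: mm-ms-g (stress MPa)"


@dataclass
class KeywordDeck:
    """In-memory deck: mesh + beam sections + materials + unknown cards."""

    mesh: HexMesh
    sections: list[BeamSection] = field(default_factory=list)
    materials: dict[int, Material] = field(default_factory=dict)
    couplings: list[tuple[int, int]] = field(default_factory=list)  # (beam part, solid part)
    extra_cards: list[str] = field(default_factory=list)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _validate(mesh: HexMesh, sections: list[BeamSection]) -> None:
    n = mesh.node_coords.shape[0]
    offenders = []
    for name, arr in (
        ("solid", mesh.solid_elems),
        ("shell", mesh.shell_elems),
        ("beam", mesh.beam_elems),
    ):
        if arr.size and (arr.min() < 0 or arr.max() >= n):
            bad = np.unique(arr[(arr < 0) | (arr >= n)])
            offenders.append(f"{name} elements reference missing nodes {bad.tolist()}")
    if mesh.beam_elems.size:
        if mesh.beam_sections.size and sections:
            if mesh.beam_sections.max(initial=-1) >= len(sections):
                offenders.append("beam elements reference missing sections")
    if offenders:
        raise ValueError("dangling ids: " + "; ".join(offenders))


def write_keyword(
    mesh: HexMesh,
    sections: list[BeamSection] | None = None,
    materials: dict[int, Material] | None = None,
    path=None,
    beam_mesh: BeamMesh | None = None,
    extra_cards: list[str] | None = None,
) -> str:
    """Serialise a mesh (optionally with vein beams) to a keyword deck.

    If ``beam_mesh`` is given, its elements/sections are appended to the
    mesh under a new part and a ``*CONSTRAINED_BEAM_IN_SOLID`` card ties
    the beam part to every brain solid part.  Returns the deck text;
    writes it to ``path`` when given.
    """
    sections = list(sections or [])
    mesh = mesh.copy()
    couplings: list[tuple[int, int]] = []

    if beam_mesh is not None:
        base = mesh.node_coords.shape[0]
        mesh.node_coords = np.vstack([mesh.node_coords, beam_mesh.tree.node_positions])
        mesh.beam_elems = np.vstack([
            mesh.beam_elems, beam_mesh.elements + base
        ]).astype(np.int64)
        first_sid = len(sections)
        sections.extend(beam_mesh.sections)
        mesh.beam_sections = np.concatenate([
            mesh.beam_sections,
            first_sid + np.arange(len(beam_mesh.sections), dtype=np.int64),
        ])
        vein_pid = max([0, *mesh.part_names.keys()]) + 1
        mesh.part_names[vein_pid] = "veins"
        if beam_mesh.couple_to_solid:
            from .image import role_ids

            brain = role_ids(mesh.part_names)["brain"]
            for pid in sorted(brain) or sorted({int(p) for p in np.unique(mesh.solid_parts)}):
                couplings.append((vein_pid, pid))

    _validate(mesh, sections)

    lines: list[str] = ["*KEYWORD", _HEADER]
    lines.append("*NODE")
    for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    if mesh.solid_elems.size:
        lines.append("*ELEMENT_SOLID")
        for eid, (el, pid) in enumerate(zip(mesh.solid_elems, mesh.solid_parts), start=1):
            lines.append(f"{eid},{int(pid)}," + ",".join(str(int(n) + 1) for n in el))
    if mesh.shell_elems.size:
        lines.append("*ELEMENT_SHELL")
        for eid, (el, pid, th) in enumerate(
            zip(mesh.shell_elems, mesh.shell_parts, mesh.shell_thickness), start=1
        ):
            lines.append(
                f"{eid},{int(pid)},"
                + ",".join(str(int(n) + 1) for n in el)
                + f",{_fmt(float(th))}"
            )
    if mesh.beam_elems.size:
        lines.append("*ELEMENT_BEAM")
        vein_pid = max(mesh.part_names.keys(), default=1)
        for eid, (el, sid) in enumerate(zip(mesh.beam_elems, mesh.beam_sections), start=1):
            lines.append(
                f"{eid},{vein_pid},{int(el[0]) + 1},{int(el[1]) + 1},{int(sid) + 1}"
            )
    for sid, sec in enumerate(sections, start=1):
        lines.append("*SECTION_BEAM")
        lines.append(f"{sid},1")  # sid, tubular element formulation
        d, di = sec.outer_diameter_mm, sec.inner_diameter_mm
        lines.append(f"{_fmt(d)},{_fmt(d)},{_fmt(di)},{_fmt(di)}")
    if materials:
        for mid, mat in sorted(materials.items()):
            lines.append("*MAT_ELASTIC")
            # density in g/mm^3 for the mm-ms-g system
            rho_g_mm3 = mat.rho_kg_m3 * 1e-6
            lines.append(f"{mid},{rho_g_mm3:.9f},{_fmt(mat.e_mpa)},{_fmt(mat.nu)}")
    for pid in sorted(mesh.part_names):
        lines.append("*PART")
        lines.append(mesh.part_names[pid])
        lines.append(f"{pid},0,0")
    for beam_pid, solid_pid in couplings:
        lines.append("*CONSTRAINED_BEAM_IN_SOLID")
        lines.append(f"{beam_pid},{solid_pid}")
    for card in extra_cards or []:
        lines.append(card.rstrip("\n"))
    lines.append("*END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_keyword(path_or_text) -> KeywordDeck:
    """Parse a deck written by :func:`write_keyword` (dialect subset).

    Unknown cards are preserved verbatim (and re-emitted on write) with
    a warning.  Malformed cards raise with their line number.
    """
    try:
        text = open(path_or_text).read()
    except (OSError, TypeError):
        text = str(path_or_text)
    lines = text.splitlines()

    nodes: list[tuple[int, float, float, float]] = []
    solids: list[tuple[int, list[int]]] = []
    shells: list[tuple[int, list[int], float]] = []
    beams: list[tuple[int, int, int, int]] = []
    sections: dict[int, BeamSection] = {}
    materials: dict[int, Material] = {}
    part_names: dict[int, str] = {}
    couplings: list[tuple[int, int]] = []
    extra: list[str] = []

    known = {
        "*KEYWORD", "*END", "*NODE", "*ELEMENT_SOLID", "*ELEMENT_SHELL",
        "*ELEMENT_BEAM", "*SECTION_BEAM", "*MAT_ELASTIC", "*PART",
        "*CONSTRAINED_BEAM_IN_SOLID",
    }

    i = 0
    card = None
    pending: list[str] = []

    def parse_err(lineno: int, msg: str):
        raise ValueError(f"line {lineno + 1}: {msg}")

    while i < len(lines):
        raw = lines[i]
        line = raw.strip()
        if not line or line.startswith("$"):
            i += 1
            continue
        if line.startswith("*"):
            card = line.upper()
            pending = []
            if card not in known:
                warnings.warn(f"unknown card {card} preserved verbatim", stacklevel=2)
                extra.append(raw)
                # swallow its data lines too
                j = i + 1
                while j < len(lines) and not lines[j].strip().startswith("*"):
                    extra.append(lines[j])
                    j += 1
                i = j
                card = None
                continue
            i += 1
            continue
        if card is None:
            parse_err(i, f"data line outside any card: {line!r}")
        fields = [f.strip() for f in line.replace("\t", ",").split(",") if f.strip() != ""]
        try:
            if card == "*NODE":
                nid, x, y, z = int(fields[0]), *map(float, fields[1:4])
                nodes.append((nid, x, y, z))
            elif card == "*ELEMENT_SOLID":
                pid = int(fields[1])
                solids.append((pid, [int(f) for f in fields[2:10]]))
            elif card == "*ELEMENT_SHELL":
                pid = int(fields[1])
                conn = [int(f) for f in fields[2:6]]
                th = float(fields[6]) if len(fields) > 6 else 0.0
                shells.append((pid, conn, th))
            elif card == "*ELEMENT_BEAM":
                beams.append((int(fields[1]), int(fields[2]), int(fields[3]), int(fields[4])))
            elif card == "*SECTION_BEAM":
                pending.append(line)
                if len(pending) == 2:
                    sid = int(pending[0].split(",")[0])
                    ts1, _ts2, tt1, _tt2 = map(float, pending[1].split(","))
                    h = (ts1 - tt1) / 2
                    sections[sid] = BeamSection(ts1, h)
                    pending = []
            elif card == "*MAT_ELASTIC":
                mid = int(fields[0])
                rho_g_mm3, e, nu = map(float, fields[1:4])
                materials[mid] = Material(e_mpa=e, nu=nu, rho_kg_m3=rho_g_mm3 * 1e6)
            elif card == "*PART":
                pending.append(line)
                if len(pending) == 2:
                    pid = int(pending[1].split(",")[0])
                    part_names[pid] = pending[0]
                    pending = []
            elif card == "*CONSTRAINED_BEAM_IN_SOLID":
                couplings.append((int(fields[0]), int(fields[1])))
        except (ValueError, IndexError) as exc:
            if isinstance(exc, ValueError) and str(exc).startswith("line "):
                raise
            parse_err(i, f"malformed {card} card: {line!r}")
        i += 1

    if not nodes:
        warnings.warn("deck contains no nodes: empty mesh", stacklevel=2)
        mesh = HexMesh(
            node_coords=np.empty((0, 3)),
            solid_elems=np.empty((0, 8), dtype=np.int64),
            solid_parts=np.empty(0, dtype=np.int64),
            part_names=part_names,
        )
        return KeywordDeck(mesh, [], materials, couplings, extra)

    ids = np.array([n[0] for n in nodes])
    coords = np.array([[n[1], n[2], n[3]] for n in nodes])
    id_to_row = {int(nid): r for r, nid in enumerate(ids)}

    def rows(conn):
        return [id_to_row[c] for c in conn]

    solid_elems = np.array([rows(c) for _, c in solids], dtype=np.int64).reshape(-1, 8)
    solid_parts = np.array([p for p, _ in solids], dtype=np.int64)
    shell_elems = np.array([rows(c) for _, c, _ in shells], dtype=np.int64).reshape(-1, 4)
    shell_parts = np.array([p for p, _, _ in shells], dtype=np.int64)
    shell_thick = np.array([t for _, _, t in shells], dtype=float)
    beam_elems = np.array([[id_to_row[a], id_to_row[b]] for _, a, b, _ in beams],
                          dtype=np.int64).reshape(-1, 2)
    beam_sids = np.array([s - 1 for _, _, _, s in beams], dtype=np.int64)

    mesh = HexMesh(
        node_coords=coords,
        solid_elems=solid_elems,
        solid_parts=solid_parts,
        shell_elems=shell_elems,
        shell_parts=shell_parts,
        shell_thickness=shell_thick,
        beam_elems=beam_elems,
        beam_sections=beam_sids,
        part_names=part_names,
    )
    ordered_sections = [sections[s] for s in sorted(sections)]
    return KeywordDeck(mesh, ordered_sections, materials, couplings, extra)
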
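"""SBGN-ML reading and writing for Process Description maps.

Targets the 0.2-era SBGN-ML dialect: one ``<sbgn>`` root, one ``<map>``
with ``language="process description"``, glyphs with ``class``/``label``/
``bbox``, complex membership encoded by XML nesting, compartment
membership by ``compartmentRef``, process ports as ``<port>`` children,
and arcs whose ``source``/``target`` may name either glyphs or ports.

Parsing is lossless with respect to the compound-graph structure: every
glyph's parent link is reconstructed (nesting beats compartmentRef),
every arc endpoint is resolved to the owning glyph id, auxiliary glyphs
(state variables, units of information) are attached to their owner
rather than becoming map nodes, and unknown attributes are preserved
verbatim and re-emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from lxml import etree

from .errors import (
    DanglingReferenceError,
    SbgnParseError,
    UnknownClassError,
    UnsupportedLanguageError,
    ValidationError,
)
from .model import (
    AUX_CLASSES,
    ARC_CLASSES,
    GLYPH_CLASSES,
    Arc,
    AuxGlyph,
    BBox,
    Glyph,
    PDMap,
    Port,
)

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
PD_LANGUAGE = "process description"

_KNOWN_GLYPH_ATTRS = {"id", "class", "compartmentRef", "orientation"}
_KNOWN_ARC_ATTRS = {"id", "class", "source", "target"}


@dataclass
class RawDocument:
    """An SBGN-ML document as text, plus the map identity it carries."""

    xml_text: str
    language: str = PD_LANGUAGE
    map_id: str = "map1"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _fmt(value: float) -> str:
    """Format a coordinate losslessly (repr round-trips Python floats)."""
    if math.isfinite(value) and value == int(value):
        return str(int(value))
    return repr(value)


def _parse_bbox(elem: etree._Element | None) -> BBox:
    if elem is None:
        return BBox()
    try:
        return BBox(
            x=float(elem.get("x", 0)),
            y=float(elem.get("y", 0)),
            w=float(elem.get("w", 0)),
            h=float(elem.get("h", 0)),
        )
    except ValueError as exc:
        raise SbgnParseError(f"bad bbox at line {elem.sourceline}: {exc}") from exc


def parse_sbgnml(raw: RawDocument | str) -> PDMap:
    """Parse an SBGN-ML PD document into a :class:`PDMap`.

    Raises :class:`SbgnParseError` (malformed XML, naming the line),
    :class:`UnsupportedLanguageError` (non-PD map),
    :class:`UnknownClassError` (glyph/arc class outside the PD vocabulary)
    or :class:`DanglingReferenceError` (arc endpoint or compartmentRef
    naming nothing).
    """
    xml_text = raw.xml_text if isinstance(raw, RawDocument) else raw
    try:
        root = etree.fromstring(xml_text.encode() if isinstance(xml_text, str) else xml_text)
    except etree.XMLSyntaxError as exc:
        raise SbgnParseError(f"malformed XML: {exc}") from exc
    if _local(root.tag) != "sbgn":
        raise SbgnParseError(f"expected <sbgn> root, found <{_local(root.tag)}>")
    maps = [c for c in root if _local(c.tag) == "map"]
    if len(maps) != 1:
        raise SbgnParseError(f"expected exactly one <map>, found {len(maps)}")
    map_elem = maps[0]
    language = map_elem.get("language", "")
    if language != PD_LANGUAGE:
        raise UnsupportedLanguageError(
            f"unsupported map language {language!r}; only {PD_LANGUAGE!r} is supported"
        )

    pd_map = PDMap(map_elem.get("id", "map1"))
    compartment_refs: dict[str, str] = {}

    def _read_glyph(elem: etree._Element, parent_id: str | None) -> None:
        gid = elem.get("id")
        gclass = elem.get("class", "")
        if gid is None:
            raise SbgnParseError(f"glyph without id at line {elem.sourceline}")
        if gclass in AUX_CLASSES:
            # auxiliary units are attached to the owner, never map nodes
            return
        if gclass not in GLYPH_CLASSES:
            raise UnknownClassError(f"glyph {gid!r} has unknown class {gclass!r}")
        label = ""
        bbox_elem = None
        for child in elem:
            tag = _local(child.tag)
            if tag == "label":
                label = child.get("text", "")
            elif tag == "bbox":
                bbox_elem = child
        glyph = Glyph(
            id=gid,
            glyph_class=gclass,
            label=label,
            parent_id=parent_id,
            bbox=_parse_bbox(bbox_elem),
            compartment_ref=elem.get("compartmentRef"),
            extra={k: v for k, v in elem.attrib.items() if k not in _KNOWN_GLYPH_ATTRS},
        )
        if elem.get("compartmentRef") is not None:
            compartment_refs[gid] = elem.get("compartmentRef")
        pd_map.add_glyph(glyph)
        for child in elem:
            tag = _local(child.tag)
            if tag == "glyph":
                cclass = child.get("class", "")
                if cclass in AUX_CLASSES:
                    glyph.aux.append(
                        AuxGlyph(
                            id=child.get("id", f"{gid}.aux{len(glyph.aux)}"),
                            aux_class=cclass,
                            label=next(
                                (
                                    s.get("text", s.get("value", ""))
                                    for s in child
                                    if _local(s.tag) in ("label", "state")
                                ),
                                "",
                            ),
                            bbox=_parse_bbox(
                                next((b for b in child if _local(b.tag) == "bbox"), None)
                            ),
                        )
                    )
                else:
                    # XML nesting inside a complex wins over compartmentRef
                    _read_glyph(child, gid)
            elif tag == "port":
                pid = child.get("id")
                if pid is None:
                    raise SbgnParseError(f"port without id at line {child.sourceline}")
                pd_map.add_port(
                    Port(
                        id=pid,
                        owner_glyph_id=gid,
                        x=float(child.get("x", 0)),
                        y=float(child.get("y", 0)),
                    )
                )

    for child in map_elem:
        if _local(child.tag) == "glyph":
            _read_glyph(child, None)

    # compartment membership from compartmentRef when not nested in a complex
    for gid, ref in compartment_refs.items():
        if ref not in pd_map.glyphs:
            raise DanglingReferenceError(
                f"glyph {gid!r} has compartmentRef {ref!r} naming no glyph"
            )
        if pd_map.glyphs[gid].parent_id is None:
            pd_map.set_parent(gid, ref)

    def _resolve(endpoint: str, arc_id: str) -> tuple[str, str | None]:
        if endpoint in pd_map.glyphs:
            return endpoint, None
        if endpoint in pd_map.ports:
            return pd_map.ports[endpoint].owner_glyph_id, endpoint
        raise DanglingReferenceError(
            f"arc {arc_id!r} endpoint {endpoint!r} names no glyph or port"
        )

    for child in map_elem:
        if _local(child.tag) != "arc":
            continue
        arc_id = child.get("id")
        if arc_id is None:
            raise SbgnParseError(f"arc without id at line {child.sourceline}")
        aclass = child.get("class", "")
        if aclass not in ARC_CLASSES:
            raise UnknownClassError(f"arc {arc_id!r} has unknown class {aclass!r}")
        source = child.get("source")
        target = child.get("target")
        if source is None or target is None:
            raise SbgnParseError(f"arc {arc_id!r} missing source/target")
        src_glyph, src_port = _resolve(source, arc_id)
        tgt_glyph, tgt_port = _resolve(target, arc_id)
        pd_map.add_arc(
            Arc(
                id=arc_id,
                arc_class=aclass,
                source_id=src_glyph,
                target_id=tgt_glyph,
                source_port=src_port,
                target_port=tgt_port,
                extra={k: v for k, v in child.attrib.items() if k not in _KNOWN_ARC_ATTRS},
            )
        )
    return pd_map


def write_sbgnml(pd_map: PDMap, validate: bool = True) -> RawDocument:
    """Serialize a :class:`PDMap` to SBGN-ML.

    Complex members are emitted as nested glyph elements, compartment
    membership as ``compartmentRef``, ports are re-emitted on their
    owners, and bounding boxes keep full numeric precision.  By default
    the map must pass structural validation first.
    """
    if validate:
        from .generate import validate_structure

        report = validate_structure(pd_map)
        if not report.ok:
            raise ValidationError(f"refusing to write invalid map:\n{report}")

    nsmap = {None: SBGN_NS}
    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap=nsmap)
    map_elem = etree.SubElement(
        root, f"{{{SBGN_NS}}}map", language=PD_LANGUAGE, id=pd_map.map_id
    )

    ports_by_owner: dict[str, list[Port]] = {}
    for port in pd_map.ports.values():
        ports_by_owner.setdefault(port.owner_glyph_id, []).append(port)

    def _emit_glyph(glyph: Glyph, container: etree._Element, nested: bool) -> None:
        attrs = {"id": glyph.id, "class": glyph.glyph_class}
        parent = pd_map.glyphs.get(glyph.parent_id) if glyph.parent_id else None
        if not nested and parent is not None and parent.glyph_class == "compartment":
            attrs["compartmentRef"] = parent.id
        attrs.update(glyph.extra)
        elem = etree.SubElement(container, f"{{{SBGN_NS}}}glyph", attrs)
        if glyph.label:
            etree.SubElement(elem, f"{{{SBGN_NS}}}label", text=glyph.label)
        etree.SubElement(
            elem,
            f"{{{SBGN_NS}}}bbox",
            x=_fmt(glyph.bbox.x),
            y=_fmt(glyph.bbox.y),
            w=_fmt(glyph.bbox.w),
            h=_fmt(glyph.bbox.h),
        )
        for aux in glyph.aux:
            aux_elem = etree.SubElement(
                elem, f"{{{SBGN_NS}}}glyph", id=aux.id, **{"class": aux.aux_class}
            )
            if aux.label:
                etree.SubElement(aux_elem, f"{{{SBGN_NS}}}label", text=aux.label)
            bb = aux.bbox or BBox()
            etree.SubElement(
                aux_elem,
                f"{{{SBGN_NS}}}bbox",
                x=_fmt(bb.x),
                y=_fmt(bb.y),
                w=_fmt(bb.w),
                h=_fmt(bb.h),
            )
        for port in ports_by_owner.get(glyph.id, ()):
            etree.SubElement(
                elem, f"{{{SBGN_NS}}}port", id=port.id, x=_fmt(port.x), y=_fmt(port.y)
            )
        if glyph.glyph_class == "complex":
            for child_id in sorted(pd_map.children_of(glyph.id)):
                _emit_glyph(pd_map.glyphs[child_id], elem, nested=True)

    def _top_level(glyph: Glyph) -> bool:
        if glyph.parent_id is None:
            return True
        parent = pd_map.glyphs.get(glyph.parent_id)
        return parent is not None and parent.glyph_class == "compartment"

    for glyph in pd_map.glyphs.values():
        if _top_level(glyph):
            _emit_glyph(glyph, map_elem, nested=False)

    for arc in pd_map.arcs.values():
        attrs = {
            "id": arc.id,
            "class": arc.arc_class,
            "source": arc.source_port or arc.source_id,
            "target": arc.target_port or arc.target_id,
        }
        attrs.update(arc.extra)
        arc_elem = etree.SubElement(map_elem, f"{{{SBGN_NS}}}arc", attrs)
        src_bb = pd_map.glyphs[arc.source_id].bbox
        tgt_bb = pd_map.glyphs[arc.target_id].bbox
        etree.SubElement(
            arc_elem, f"{{{SBGN_NS}}}start", x=_fmt(src_bb.cx), y=_fmt(src_bb.cy)
        )
        etree.SubElement(
            arc_elem, f"{{{SBGN_NS}}}end", x=_fmt(tgt_bb.cx), y=_fmt(tgt_bb.cy)
        )

    text = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()
    return RawDocument(xml_text=text, language=PD_LANGUAGE, map_id=pd_map.map_id)


def read_file(path: str) -> PDMap:
    """Parse an ``.sbgn`` file from disk."""
    with open(path, "rb") as fh:
        return parse_sbgnml(RawDocument(xml_text=fh.read().decode()))


def write_file(pd_map: PDMap, path: str, validate: bool = True) -> None:
    """Write a map to an ``.sbgn`` file."""
    doc = write_sbgnml(pd_map, validate=validate)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc.xml_text)
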
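"""Shared lxml helpers: hardened parsing, canonical comparison, path walks."""

from __future__ import annotations

from lxml import etree

from .errors import XmlParseError

# External entities and network fetches are disabled: study metadata and
# clinical documents routinely come from third parties.
_PARSER = etree.XMLParser(
    resolve_entities=False,
    no_network=True,
    remove_comments=False,
    remove_pis=False,
)


def parse_bytes(source: bytes) -> etree._Element:
    """Parse an XML byte stream, mapping syntax errors to :class:`XmlParseError`."""
    if isinstance(source, str):
        source = source.encode("utf-8")
    try:
        return etree.fromstring(source, parser=_PARSER)
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(
            f"malformed XML at line {exc.lineno}, column {exc.position[1]}: {exc.msg}"
        ) from exc


def local_name(element: etree._Element) -> str:
    return etree.QName(element).localname


def serialize(root: etree._Element) -> bytes:
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def canonical(tree_or_bytes) -> bytes:
    """C14N form, for logical-equality comparison of two serializations."""
    if isinstance(tree_or_bytes, bytes):
        tree_or_bytes = parse_bytes(tree_or_bytes)
    return etree.tostring(tree_or_bytes, method="c14n2")


def yes_no(flag: bool) -> str:
    return "Yes" if flag else "No"


def parse_yes_no(value: str | None, default: bool) -> bool:
    if value is None:
        return default
    return value == "Yes"


def element_paths(root: etree._Element) -> list[str]:
    """Dot-joined local-name path of every descendant element (root excluded).

    Comments and processing instructions are skipped. Returned in document
    order; repeated paths repeat (the result is a multiset).
    """
    out: list[str] = []

    def walk(el: etree._Element, prefix: tuple[str, ...]) -> None:
        for child in el:
            if not isinstance(child.tag, str):
                continue
            path = prefix + (local_name(child),)
            out.append(".".join(path))
            walk(child, path)

    walk(root, ())
    return out


def validate_against_xsd(xml_bytes: bytes, xsd_path: str) -> list[str]:
    """Validate serialized XML against a user-supplied XSD; returns messages."""
    schema = etree.XMLSchema(etree.parse(xsd_path))
    doc = etree.fromstring(xml_bytes, parser=_PARSER)
    if schema.validate(doc):
        return []
    return [str(e) for e in schema.error_log]
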
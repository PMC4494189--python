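"""Independent brute-force reference for CDA flattening.

Deliberately written as a separate, simple-minded traversal (iterative,
two-pass ordinal assignment) so it can serve as an oracle for the
production flattener without sharing its code path.
"""

from collections import Counter

XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
STRUCTURAL = {"classCode", "moodCode", "typeCode"}


def brute_force_flatten(root, skip_structural=False, skip_elements=(), max_depth=10**9):
    """Return the list of item names an exhaustive walk would produce.

    Items appear in document order: for each element (root excluded),
    retained attributes first, then its own non-whitespace text. Ordinals
    are assigned in a second pass by counting repeated base names.
    """
    records = []  # (base_name,) in document order
    stack = [(root, ())]
    while stack:
        el, path = stack.pop()
        children = [c for c in el if isinstance(c.tag, str)]
        for child in reversed(children):
            tag = child.tag.rsplit("}", 1)[-1]
            if tag in skip_elements:
                continue
            cpath = path + (tag,)
            if len(cpath) > max_depth:
                continue
            stack.append((child, cpath))

        if not path:  # the root element itself
            continue
        for attr in el.attrib:
            if attr.startswith("{" + XSI_NS + "}"):
                continue
            local = attr.rsplit("}", 1)[-1]
            if skip_structural and local in STRUCTURAL:
                continue
            records.append(".".join(path) + ".attributes." + local)
        own = (el.text or "") + "".join(c.tail or "" for c in el)
        if own.strip():
            records.append(".".join(path))

    seen = Counter()
    names = []
    for base in records:
        seen[base] += 1
        names.append(base if seen[base] == 1 else f"{base}.{seen[base]}")
    return names
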
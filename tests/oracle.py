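"""Exhaustive brute-force reference for the file↔sample matching cascade.

Written independently of the package's linker: every rule is applied
literally, per file, by enumerating all descriptor×file comparisons.
Intended only for small problems (≤10 files × ≤10 samples).
"""

from __future__ import annotations

import re


def _lower(s: str) -> str:
    return s.strip().lower()


def _basename(p: str) -> str:
    p = p.replace("\\", "/")
    return p.split("/")[-1]


def _noext(name: str) -> str:
    if "." in name:
        return name[: name.rindex(".")]
    return name


def _parts(descriptor: str, separators) -> list[str]:
    chunks = re.split("|".join(re.escape(s) for s in separators), descriptor)
    return [c.strip() for c in chunks if c.strip()]


def brute_force_linkage(files, descriptors, separators=(",", ";", "|")):
    """Return (links, ambiguous, unlinked) exactly per the tier rules.

    links: dict file → (tier_name, sample); ambiguous and unlinked are sets.
    """

    def predicates(descriptor, file_path):
        # ordered (tier label, does-this-descriptor-match) pairs
        d, f = _lower(descriptor), _lower(file_path)
        yield "full_path", d == f
        yield "base_name", _lower(_basename(descriptor)) == _lower(_basename(file_path))
        yield "base_name_no_ext", (_lower(_noext(_basename(descriptor)))
                                   == _lower(_noext(_basename(file_path))))
        split = _parts(descriptor, separators)
        yield "separator_split:full", any(_lower(p) == f for p in split)
        yield "separator_split:base", any(
            _lower(_basename(p)) == _lower(_basename(file_path)) for p in split)
        yield "separator_split:noext", any(
            _lower(_noext(_basename(p))) == _lower(_noext(_basename(file_path)))
            for p in split)

    stage_labels = ["full_path", "base_name", "base_name_no_ext",
                    "separator_split", "separator_split", "separator_split"]
    links: dict[str, tuple[str, str]] = {}
    ambiguous: set[str] = set()
    decided: set[str] = set()

    for stage, label in enumerate(stage_labels):
        for file_path in files:
            if file_path in decided:
                continue
            hits = set()
            for sample, values in descriptors.items():
                for value in values:
                    if list(predicates(value, file_path))[stage][1]:
                        hits.add(sample)
            if not hits:
                continue
            decided.add(file_path)
            if len(hits) == 1:
                links[file_path] = (label, hits.pop())
            else:
                ambiguous.add(file_path)

    # substring stage over the survivors, with both uniqueness guards
    survivors = [f for f in files if f not in decided]
    matches = {}  # file → set of samples
    for file_path in survivors:
        stem = _lower(_noext(_basename(file_path)))
        hit_samples = set()
        for sample, values in descriptors.items():
            for value in values:
                frag = _lower(_noext(_basename(value)))
                if min(len(frag), len(stem)) < 4:
                    continue
                if frag in stem or stem in frag:
                    hit_samples.add(sample)
        matches[file_path] = hit_samples

    unlinked = set()
    for file_path in survivors:
        hit_samples = matches[file_path]
        if not hit_samples:
            unlinked.add(file_path)
        elif len(hit_samples) > 1:
            ambiguous.add(file_path)
        else:
            sample = next(iter(hit_samples))
            owners = [f for f in survivors if sample in matches[f]]
            if len(owners) > 1:
                ambiguous.add(file_path)
            else:
                links[file_path] = ("substring", sample)
    return links, ambiguous, unlinked
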
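"""Function catalogs: KO->pathway maps, the bundled GH role map, urea KO sets."""

from __future__ import annotations

from importlib import resources

import yaml

from .io import _header
from .model import FunctionCatalog, ValidationError


def _data_path(name: str):
    return resources.files("mgcompare.data").joinpath(name)


def load_gh_categories() -> dict[str, str]:
    """Bundled GH family -> lignocellulose-role map (33 families)."""
    out: dict[str, str] = {}
    with resources.as_file(_data_path("gh_categories.tsv")) as p:
        header, it = _header(str(p), ["family", "category"])
        fi, ci = header.index("family"), header.index("category")
        for lineno, fields in it:
            cat = fields[ci]
            if cat not in FunctionCatalog.LIGNO_CATEGORIES:
                raise ValidationError(f"gh_categories.tsv:{lineno}: bad category {cat}")
            out[fields[fi]] = cat
    return out


def load_crossbiome_profiles() -> dict[str, dict[str, float]]:
    """Published per-family GH percentages, column -> {family: percent}."""
    with resources.as_file(_data_path("gh_profiles_crossbiome.tsv")) as p:
        header, it = _header(str(p), ["family"])
        biomes = [c for c in header if c != "family"]
        out: dict[str, dict[str, float]] = {b: {} for b in biomes}
        for _, fields in it:
            fam = fields[header.index("family")]
            for b in biomes:
                out[b][fam] = float(fields[header.index(b)])
    return out


def load_urea_config(path: str | None = None) -> dict[str, frozenset[str]]:
    """Named KO sets for the urea screen; bundled defaults unless overridden."""
    if path is None:
        with resources.as_file(_data_path("urea_kos.yaml")) as p:
            raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    required = {"urt_subunits", "utp", "urease_structural", "urease_accessory"}
    if not isinstance(raw, dict) or not required <= set(raw):
        raise ValidationError(f"urea config must define {sorted(required)}")
    out: dict[str, frozenset[str]] = {}
    for key in required:
        kos = raw[key]
        if not isinstance(kos, list) or not all(isinstance(k, str) for k in kos):
            raise ValidationError(f"urea config: {key} must be a list of KO ids")
        out[key] = frozenset(kos)
    return out


def read_ko_pathway_table(path: str) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """KO->pathway catalog TSV: columns ko, pathway, category."""
    header, it = _header(path, ["ko", "pathway", "category"])
    ki, pi, ci = (header.index(c) for c in ("ko", "pathway", "category"))
    ko_to_pathways: dict[str, set[str]] = {}
    pathway_category: dict[str, str] = {}
    for _, fields in it:
        ko_to_pathways.setdefault(fields[ki], set()).add(fields[pi])
        pathway_category[fields[pi]] = fields[ci]
    return (
        {k: frozenset(v) for k, v in ko_to_pathways.items()},
        pathway_category,
    )


def write_ko_pathway_table(catalog: FunctionCatalog, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ko\tpathway\tcategory\n")
        for ko in sorted(catalog.ko_to_pathways):
            for pw in sorted(catalog.ko_to_pathways[ko]):
                cat = catalog.pathway_category.get(pw, "")
                fh.write(f"{ko}\t{pw}\t{cat}\n")


def default_catalog(
    ko_to_pathways: dict[str, frozenset[str]] | None = None,
    pathway_category: dict[str, str] | None = None,
    min_kos_per_pathway: int = 3,
) -> FunctionCatalog:
    """Catalog with the bundled GH role map and an optional KO->pathway table."""
    return FunctionCatalog(
        ko_to_pathways=dict(ko_to_pathways or {}),
        pathway_category=dict(pathway_category or {}),
        gh_category=load_gh_categories(),
        min_kos_per_pathway=min_kos_per_pathway,
    )
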
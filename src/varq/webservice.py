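"""Stateless HTTP front-end over the query layer.

Every query is a bookmarkable URL: the service holds no session state, so
two requests with the same URL against an unchanged store return identical
bytes.  Responses are XML metadata documents (which embed enough URLs to
navigate the whole service), or plain BED/WIG/tag-list bodies identical to
what the library/CLI exports for the same query, plus genome-browser links
that wrap a service URL as a loadable custom track.

Routes (frozen; parameters are validated, unknown ones rejected with 400):

    GET /                                     HTML index
    GET /genomes                              XML genome/metadata listing
    GET /genomes/{label}/variants             ?region&format=bed|tsv|tags|xml
                                              &tag&tag.value&filter.minObs
                                              &filter.minDepth&filter.maxP
                                              &filter.type&offset&limit
    GET /genomes/{label}/consequences         ?region&format=xml|tsv + filter.*
    GET /genomes/{label}/coverage             ?region (required)
                                              &format=wig|wig-block

Region strings are contig:start-stop, 0-based half-open (the library
convention).  The app is a plain WSGI callable; ``serve`` wraps it in
wsgiref for the CLI, bound to localhost by default, no authentication.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from typing import Callable
from urllib.parse import parse_qsl, quote, urlencode
from wsgiref.simple_server import make_server

from .datamodel import VariantType
from .engine import QueryEngine
from .kvstore import UnknownGenomeError
from .query_export import (
    RegionParseError,
    VariantFilter,
    export_bed,
    export_tsv,
    export_wig,
    nonredundant_tags,
    query_consequences,
    query_coverage,
    query_variants,
)

SCHEMA_VERSION = "1"


class HTTPError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message
        super().__init__(message)


_FILTER_PARAMS = {
    "filter.minObs",
    "filter.minDepth",
    "filter.maxP",
    "filter.type",
    "tag",
    "tag.value",
}
_VARIANT_PARAMS = _FILTER_PARAMS | {"region", "format", "offset", "limit"}
_CONSEQUENCE_PARAMS = _FILTER_PARAMS | {"region", "format"}
_COVERAGE_PARAMS = {"region", "format"}

_STATUS = {200: "200 OK", 400: "400 Bad Request", 404: "404 Not Found"}


def _parse_int(params: dict, key: str) -> int | None:
    if key not in params:
        return None
    try:
        return int(params[key])
    except ValueError:
        raise HTTPError(400, f"parameter {key} must be an integer") from None


def build_filter(params: dict[str, str]) -> VariantFilter:
    max_p = None
    if "filter.maxP" in params:
        try:
            max_p = float(params["filter.maxP"])
        except ValueError:
            raise HTTPError(400, "parameter filter.maxP must be a number") from None
    types = None
    if "filter.type" in params:
        try:
            types = frozenset(
                VariantType(t) for t in params["filter.type"].split(",") if t
            )
        except ValueError as e:
            raise HTTPError(400, f"bad filter.type: {e}") from None
    return VariantFilter(
        min_observations=_parse_int(params, "filter.minObs"),
        min_depth=_parse_int(params, "filter.minDepth"),
        max_p_value=max_p,
        variant_types=types,
        tag=params.get("tag"),
        tag_value=params.get("tag.value"),
    )


class VarqService:
    """WSGI application over one open engine."""

    def __init__(self, engine: QueryEngine, base_url: str = ""):
        self.engine = engine
        self.base_url = base_url.rstrip("/")

    # -- plumbing ---------------------------------------------------------

    def __call__(self, environ, start_response):
        try:
            if environ.get("REQUEST_METHOD", "GET") != "GET":
                raise HTTPError(400, "only GET is supported")
            path = environ.get("PATH_INFO", "/")
            raw = parse_qsl(environ.get("QUERY_STRING", ""), keep_blank_values=True)
            params: dict[str, str] = {}
            for k, v in raw:
                if k in params:
                    raise HTTPError(400, f"duplicate parameter {k}")
                params[k] = v
            body, ctype = self._dispatch(path, params)
        except HTTPError as e:
            start_response(
                _STATUS[e.status], [("Content-Type", "text/plain; charset=utf-8")]
            )
            return [f"error: {e.message}\n".encode("utf-8")]
        data = body.encode("utf-8")
        start_response(
            _STATUS[200],
            [("Content-Type", ctype), ("Content-Length", str(len(data)))],
        )
        return [data]

    def _dispatch(self, path: str, params: dict) -> tuple[str, str]:
        parts = [p for p in path.split("/") if p]
        if not parts:
            return self._index()
        if parts == ["genomes"]:
            if params:
                raise HTTPError(400, f"unknown parameters: {sorted(params)}")
            return self._genomes()
        if len(parts) == 3 and parts[0] == "genomes":
            label, kind = parts[1], parts[2]
            try:
                if kind == "variants":
                    return self._variants(label, params)
                if kind == "consequences":
                    return self._consequences(label, params)
                if kind == "coverage":
                    return self._coverage(label, params)
            except UnknownGenomeError as e:
                raise HTTPError(404, str(e)) from None
            except RegionParseError as e:
                raise HTTPError(400, str(e)) from None
        raise HTTPError(404, f"no such resource {path!r}")

    def _check_params(self, params: dict, allowed: set) -> None:
        unknown = set(params) - allowed
        if unknown:
            raise HTTPError(
                400,
                f"unknown parameters: {sorted(unknown)}; allowed: {sorted(allowed)}",
            )

    def _url(self, path: str, **params) -> str:
        q = urlencode({k: v for k, v in params.items() if v is not None})
        return f"{self.base_url}{path}" + (f"?{q}" if q else "")

    # -- endpoints --------------------------------------------------------

    def _index(self) -> tuple[str, str]:
        items = "".join(
            f'<li><a href="{self._url(f"/genomes/{lab}/variants", format="bed")}">'
            f"{lab}</a></li>"
            for lab in self.engine.store.labels()
        )
        html = (
            "<html><head><title>variant query engine</title></head><body>"
            f"<h1>variant query engine</h1><p>reference: {self.engine.table}</p>"
            f'<p><a href="{self._url("/genomes")}">XML genome listing</a></p>'
            f"<ul>{items}</ul></body></html>"
        )
        return html, "text/html; charset=utf-8"

    def _genomes(self) -> tuple[str, str]:
        root = ET.Element("queryEngine", version=SCHEMA_VERSION)
        root.set("reference", self.engine.table)
        contigs = self.engine.store.contig_names()
        for lab in self.engine.store.labels():
            g = ET.SubElement(root, "genome", label=lab)
            ET.SubElement(
                g, "query", type="variants", formats="bed,tsv,tags,xml",
                url=self._url(f"/genomes/{lab}/variants", format="bed"),
            )
            ET.SubElement(
                g, "query", type="consequences", formats="xml,tsv",
                url=self._url(f"/genomes/{lab}/consequences", format="xml"),
            )
            if contigs:
                region = f"{contigs[0]}:0-1000"
                ET.SubElement(
                    g, "query", type="coverage", formats="wig,wig-block",
                    url=self._url(
                        f"/genomes/{lab}/coverage", region=region, format="wig"
                    ),
                )
        return ET.tostring(root, encoding="unicode"), "text/xml; charset=utf-8"

    def _variants(self, label: str, params: dict) -> tuple[str, str]:
        self._check_params(params, _VARIANT_PARAMS)
        fmt = params.get("format", "xml")
        filt = build_filter(params)
        region = params.get("region")
        offset = _parse_int(params, "offset") or 0
        limit = _parse_int(params, "limit")
        variants = list(query_variants(self.engine, label, region, filt))
        page = variants[offset : offset + limit if limit is not None else None]
        if fmt == "bed":
            buf = io.StringIO()
            export_bed(page, buf)
            return buf.getvalue(), "text/plain; charset=utf-8"
        if fmt == "tsv":
            buf = io.StringIO()
            export_tsv(page, buf)
            return buf.getvalue(), "text/plain; charset=utf-8"
        if fmt == "tags":
            lines = "".join(
                (f"{k}\t{v}\n" if v else f"{k}\n") for k, v in nonredundant_tags(page)
            )
            return lines, "text/plain; charset=utf-8"
        if fmt == "xml":
            root = ET.Element(
                "variants", genome=label, total=str(len(variants)),
                offset=str(offset), returned=str(len(page)),
            )
            for v in page:
                ET.SubElement(
                    root, "variant",
                    contig=v.locus.contig, start=str(v.locus.position),
                    stop=str(v.stop), type=v.variant_type.value,
                    ref=v.ref_allele, alt=v.alt_allele,
                    obs=str(v.observation_count), depth=str(v.depth),
                    version=str(v.version),
                )
            if limit is not None and offset + limit < len(variants):
                keep = {k: v for k, v in params.items() if k != "offset"}
                ET.SubElement(
                    root, "link", rel="next",
                    url=self._url(
                        f"/genomes/{label}/variants", offset=offset + limit, **keep
                    ),
                )
            return ET.tostring(root, encoding="unicode"), "text/xml; charset=utf-8"
        raise HTTPError(400, f"unknown format {fmt!r} for variants")

    def _consequences(self, label: str, params: dict) -> tuple[str, str]:
        self._check_params(params, _CONSEQUENCE_PARAMS)
        fmt = params.get("format", "xml")
        filt = build_filter(params)
        pairs = list(query_consequences(self.engine, label, params.get("region"), filt))
        if fmt == "tsv":
            out = ["contig\tposition\teffect\tgene\tvariant_version\n"]
            for c, v in pairs:
                out.append(
                    f"{c.locus.contig}\t{c.locus.position}\t{c.effect}\t"
                    f"{c.gene or '.'}\t{v.version}\n"
                )
            return "".join(out), "text/plain; charset=utf-8"
        if fmt == "xml":
            root = ET.Element("consequences", genome=label, count=str(len(pairs)))
            for c, v in pairs:
                ET.SubElement(
                    root, "consequence",
                    contig=c.locus.contig, position=str(c.locus.position),
                    effect=c.effect, gene=c.gene or "",
                    variantType=v.variant_type.value, variantVersion=str(v.version),
                )
            return ET.tostring(root, encoding="unicode"), "text/xml; charset=utf-8"
        raise HTTPError(400, f"unknown format {fmt!r} for consequences")

    def _coverage(self, label: str, params: dict) -> tuple[str, str]:
        self._check_params(params, _COVERAGE_PARAMS)
        if "region" not in params:
            raise HTTPError(400, "coverage queries require a region parameter")
        fmt = params.get("format", "wig")
        if fmt not in ("wig", "wig-block"):
            raise HTTPError(400, f"unknown format {fmt!r} for coverage")
        region = params["region"]
        contig = region.split(":")[0]
        cov = query_coverage(self.engine, label, region)
        buf = io.StringIO()
        if fmt == "wig":
            export_wig(cov, buf, contig, mode="per_base")
        else:
            export_wig(
                cov, buf, contig, mode="block_average",
                block_size=self.engine.store.block_size,
            )
        return buf.getvalue(), "text/plain; charset=utf-8"


def browser_link(kind: str, query_url: str) -> str:
    """A genome-browser link that loads a service query as a custom track
    (the inner URL is percent-encoded and survives a decode round-trip)."""
    if kind == "ucsc":
        return (
            "https://genome.ucsc.edu/cgi-bin/hgTracks?hgct_customText="
            + quote(query_url, safe="")
        )
    if kind == "igv":
        return "http://localhost:60151/load?file=" + quote(query_url, safe="")
    raise ValueError(f"unsupported browser kind {kind!r} (use 'ucsc' or 'igv')")


def serve(
    engine: QueryEngine,
    host: str = "127.0.0.1",
    port: int = 8080,
    app_factory: Callable[[QueryEngine, str], VarqService] = VarqService,
):
    """Run the WSGI app under wsgiref (single-threaded, localhost)."""
    app = app_factory(engine, f"http://{host}:{port}")
    httpd = make_server(host, port, app)
    return httpd
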
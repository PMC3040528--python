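"""The stateless HTTP query interface.

Every query is a URL; the WSGI app returns XML metadata or plain BED/WIG
bodies identical to the library's own export, plus genome-browser links
that wrap a query URL as a loadable custom track.  Here the app is invoked
in-process; ``varq serve`` runs the same app behind a real socket.
"""

import tempfile

from varq import QueryEngine
from varq import fixtures
from varq.importers import load_pileup
from varq.webservice import VarqService, browser_link

ref = fixtures.generate_reference([("chrX", 10_000)], seed=3)
lines, _ = fixtures.generate_pileup(ref, mean_depth=15, snv_rate=1e-3, seed=3)
engine = QueryEngine.create(tempfile.mkdtemp(), "example-ref")
load_pileup(engine, lines, "g1")
app = VarqService(engine, "http://localhost:8080")


def get(path, qs=""):
    status = []
    body = b"".join(
        app({"REQUEST_METHOD": "GET", "PATH_INFO": path, "QUERY_STRING": qs},
            lambda s, h: status.append(s))
    )
    return status[0], body.decode()


status, xml = get("/genomes")
print(f"GET /genomes -> {status}")
print(xml[:200] + "...\n")

status, bed = get("/genomes/g1/variants", "region=chrX:0-10000&format=bed&filter.minObs=3")
print(f"GET variants (>=3 observations) -> {status}, {len(bed.splitlines())} BED lines")
print("\n".join(bed.splitlines()[:2]))

url = "http://localhost:8080/genomes/g1/variants?format=bed"
print("\nUCSC custom-track link:")
print(browser_link("ucsc", url))
engine.close()
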
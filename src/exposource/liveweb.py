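"""Live web adapters: Wikipedia, NCBI E-utilities (PubMed), PubChem PUG REST.

These speak the public JSON/XML APIs over stdlib ``urllib`` and satisfy the
same :class:`~exposource.retrieval.TextSourceAdapter` protocol as the fixture
adapters, so a batch can switch between offline and live corpora by swapping
the adapter set. Network access and service availability are the caller's
responsibility; the test suite never touches these classes.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET

from .retrieval import TransportError

_USER_AGENT = "exposource/0.1 (chemical exposure-source classification)"
_TIMEOUT = 30.0


def _get(url: str, *, none_on_404: bool = False) -> bytes | None:
    request = urllib.request.Request(url, headers={"User-Agent": _USER_AGENT})
    try:
        with urllib.request.urlopen(request, timeout=_TIMEOUT) as response:
            return response.read()
    except urllib.error.HTTPError as exc:
        if none_on_404 and exc.code == 404:
            return None
        raise TransportError(f"GET {url} failed: {exc}") from exc
    except (urllib.error.URLError, TimeoutError, OSError) as exc:
        raise TransportError(f"GET {url} failed: {exc}") from exc


class LiveWikipediaAdapter:
    """Plain-text page extracts via the Wikipedia action API.

    Follows redirects; disambiguation pages are reported as a miss.
    """

    API = "https://en.wikipedia.org/w/api.php"

    def lookup(self, term: str) -> dict | None:
        params = urllib.parse.urlencode(
            {
                "action": "query",
                "prop": "extracts|pageprops",
                "explaintext": 1,
                "redirects": 1,
                "format": "json",
                "titles": term,
            }
        )
        payload = json.loads(_get(f"{self.API}?{params}"))
        pages = payload.get("query", {}).get("pages", {})
        for page_id, page in pages.items():
            if page_id == "-1" or "missing" in page:
                return None
            if "disambiguation" in page.get("pageprops", {}):
                return None
            text = page.get("extract", "")
            if not text.strip():
                return None
            return {"title": page.get("title", term), "text": text}
        return None


class LivePubMedAdapter:
    """Top abstracts via NCBI E-utilities (esearch + efetch), in PubMed's
    relevance-sorted order."""

    ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

    def __init__(self, max_hits: int = 3):
        self.max_hits = max_hits

    def lookup(self, term: str) -> list[dict] | None:
        params = urllib.parse.urlencode(
            {
                "db": "pubmed",
                "term": term,
                "retmax": self.max_hits,
                "sort": "relevance",
                "retmode": "json",
            }
        )
        search = json.loads(_get(f"{self.ESEARCH}?{params}"))
        ids = search.get("esearchresult", {}).get("idlist", [])
        if not ids:
            return None
        params = urllib.parse.urlencode(
            {"db": "pubmed", "id": ",".join(ids), "rettype": "abstract", "retmode": "xml"}
        )
        tree = ET.fromstring(_get(f"{self.EFETCH}?{params}"))
        abstracts = []
        for article in tree.iter("PubmedArticle"):
            pmid = article.findtext(".//PMID", default="")
            title = article.findtext(".//ArticleTitle", default="")
            text = " ".join(
                "".join(node.itertext()) for node in article.findall(".//AbstractText")
            )
            if text.strip():
                abstracts.append({"pmid": pmid, "title": title, "text": text})
        return abstracts or None


class LivePubChemSynonymAdapter:
    """Synonym lists via PubChem PUG REST, in PubChem's listed order."""

    API = "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/name/{}/synonyms/JSON"

    def lookup(self, term: str) -> list[str] | None:
        url = self.API.format(urllib.parse.quote(term))
        body = _get(url, none_on_404=True)  # PubChem answers 404 for unknown names
        if body is None:
            return None
        payload = json.loads(body)
        info = payload.get("InformationList", {}).get("Information", [])
        if not info:
            return None
        return list(info[0].get("Synonym", [])) or None
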
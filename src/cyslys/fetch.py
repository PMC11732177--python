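"""Convenience download of AlphaFold DB models and PAE matrices.

All core operations work from local files; this helper exists for users who
want to pull the model + PAE for a UniProt accession directly from the public
database. A local cache directory is honored first, so previously fetched (or
manually provided) files are reused without network access.
"""

from __future__ import annotations

import logging
import urllib.request
from pathlib import Path

logger = logging.getLogger(__name__)

ALPHAFOLD_FILES_URL = "https://alphafold.ebi.ac.uk/files"
MODEL_VERSION = 4

__all__ = ["fetch_alphafold_model"]


def fetch_alphafold_model(
    accession: str,
    dest_dir: str | Path,
    cache_dir: str | Path | None = None,
    timeout: float = 60.0,
) -> tuple[Path, Path]:
    """Obtain the AF-<accession>-F1 mmCIF model and PAE JSON.

    Looks in ``cache_dir`` (and ``dest_dir``) first; otherwise downloads from
    AlphaFold DB. Returns (cif_path, pae_path) inside ``dest_dir``.
    """
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    names = {
        "cif": f"AF-{accession}-F1-model_v{MODEL_VERSION}.cif",
        "pae": f"AF-{accession}-F1-predicted_aligned_error_v{MODEL_VERSION}.json",
    }
    out: dict[str, Path] = {}
    for kind, name in names.items():
        target = dest / name
        if not target.exists() and cache_dir is not None:
            cached = Path(cache_dir) / name
            if cached.exists():
                target.write_bytes(cached.read_bytes())
                logger.info("using cached %s", cached)
        if not target.exists():
            url = f"{ALPHAFOLD_FILES_URL}/{name}"
            logger.info("downloading %s", url)
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                target.write_bytes(resp.read())
        out[kind] = target
    return out["cif"], out["pae"]
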
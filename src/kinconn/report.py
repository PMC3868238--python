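"""Serialization of connectivity results: TSV, JSON, running-sum plots.

TSV output prints scores with 4 decimals and p-values with 3 so golden
files are stable; the JSON form keeps full precision and the per-drug
running-sum curves.  Writes are atomic (temp file + rename) so a failed
run never leaves a partial table behind.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import tempfile
from pathlib import Path

from . import __version__
from .connectivity import ConnectivityTable

__all__ = ["write_tsv", "write_json", "plot_running_sums", "file_sha256"]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x: float, digits: int) -> str:
    return "" if x is None or math.isnan(x) else f"{x:.{digits}f}"


def write_tsv(
    result: ConnectivityTable,
    path: str | Path,
    input_digests: dict[str, str] | None = None,
) -> None:
    """Write the ranked table with a provenance header (version, seed,
    permutation count, assay type, input-file digests)."""
    meta = result.meta
    lines = [
        f"# kinconn v{__version__}",
        f"# assay_type={meta.get('assay_type')}"
        f" permutations={meta.get('n_permutations')}"
        f" seed={meta.get('seed')}"
        f" pvalue_mode={meta.get('pvalue_mode')}",
        f"# query={','.join(meta.get('query', []))}",
    ]
    for name, digest in (input_digests or {}).items():
        lines.append(f"# sha256 {name}={digest}")
    lines.append(
        "rank\tdrug\tn_matched\tks\tscore\tnormalized_score\tp_value"
    )
    for row in result.table.itertuples():
        lines.append(
            f"{row.rank}\t{row.drug}\t{row.n_matched}\t"
            f"{_fmt(row.ks, 4)}\t{_fmt(row.score, 4)}\t"
            f"{_fmt(row.normalized_score, 4)}\t{_fmt(row.p_value, 3)}"
        )
    if result.unscored:
        lines.append("# unscored (no query kinase in profile): "
                     + ",".join(result.unscored))
    _atomic_write_text(Path(path), "\n".join(lines) + "\n")


def write_json(
    result: ConnectivityTable,
    path: str | Path,
    input_digests: dict[str, str] | None = None,
) -> None:
    """Full-precision JSON including the running-sum curve per drug."""
    payload = {
        "version": __version__,
        "meta": dict(result.meta),
        "input_digests": dict(input_digests or {}),
        "rows": [
            {
                "rank": int(r.rank),
                "drug": r.drug,
                "n_matched": int(r.n_matched),
                "ks": None if math.isnan(r.ks) else r.ks,
                "score": None if math.isnan(r.score) else r.score,
                "normalized_score": (
                    None if math.isnan(r.normalized_score)
                    else r.normalized_score
                ),
                "p_value": None if math.isnan(r.p_value) else r.p_value,
                "running_sum": [
                    float(v) for v in result.running_sums.get(r.drug, [])
                ],
            }
            for r in result.table.itertuples()
        ],
        "unscored": list(result.unscored),
    }
    _atomic_write_text(Path(path), json.dumps(payload, indent=1))


def plot_running_sums(
    result: ConnectivityTable, out_dir: str | Path, top: int = 10
) -> list[Path]:
    """Save one running-sum plot per top-ranked drug; returns the paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for row in result.table.head(top).itertuples():
        curve = result.running_sums.get(row.drug)
        if curve is None:
            continue
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(range(1, len(curve) + 1), curve, lw=1.2)
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_xlabel("rank position r")
        ax.set_ylabel("running sum D(r)")
        ax.set_title(f"{row.drug}  (ks={row.ks:.3f})")
        fig.tight_layout()
        safe = "".join(c if c.isalnum() or c in "-_." else "_"
                       for c in str(row.drug))
        p = out_dir / f"running_sum_{row.rank:03d}_{safe}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
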
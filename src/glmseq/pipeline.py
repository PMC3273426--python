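"""End-to-end pipeline: fit -> rank -> top-k -> up/down -> enrichment.

Artifacts written to the output directory:

- ``de_table.tsv``        per-contig fits, input order
- ``ranked.tsv``          full ranking
- ``top_k.tsv``           the top-k prefix
- ``up_ids.txt`` / ``down_ids.txt``  the up/down split of the top-k set
- ``enrichment_up.tsv`` / ``enrichment_down.tsv``  (when a GO mapping is
  given) enrichment of each split against all annotated contigs outside
  the test group
- ``run.log``             versions, parameters, seed and stage timings

Data artifacts are deterministic functions of the inputs and seed; the
log contains wall-clock timings and is excluded from that guarantee.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import __version__
from . import io as gio
from .enrichment import enrich
from .errors import GlmseqError
from .model import LibrarySizes, fit_table
from .ranking import count_significant, rank_results, select_top_k

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("glmseq")


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline inputs and thresholds (defaults are the analysis's)."""

    counts_path: Union[str, Path]
    library_sizes: LibrarySizes
    out_dir: Union[str, Path]
    mapping_path: Optional[Union[str, Path]] = None
    alpha: float = 0.005
    top_k: int = 5000
    screen_low: float = 10
    screen_high: float = 100
    fdr_cutoff: float = 0.05
    zero_policy: str = "haldane"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        from .errors import InvalidInputError

        if not (0 < self.alpha < 1):
            raise InvalidInputError(f"alpha must be in (0,1): {self.alpha}")
        if self.top_k < 1:
            raise InvalidInputError(f"top_k must be >= 1: {self.top_k}")
        if not (0 < self.screen_low < self.screen_high):
            raise InvalidInputError(
                "screen thresholds must satisfy 0 < low < high"
            )
        if not (0 < self.fdr_cutoff <= 1):
            raise InvalidInputError(
                f"fdr_cutoff must be in (0,1]: {self.fdr_cutoff}"
            )


def _stage(log_lines: list[str], name: str, t0: float) -> None:
    dt = time.perf_counter() - t0
    msg = f"stage {name} finished in {dt:.3f}s"
    logger.info(msg)
    log_lines.append(msg)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of artifacts.

    Any stage failure is re-raised as a :class:`GlmseqError` (or
    subclass) tagged with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    log_lines = [
        f"glmseq {__version__}",
        f"seed={config.seed}",
        f"alpha={config.alpha} top_k={config.top_k} "
        f"fdr_cutoff={config.fdr_cutoff} zero_policy={config.zero_policy}",
        f"library_sizes={config.library_sizes.totals()}",
        f"counts={config.counts_path} mapping={config.mapping_path}",
    ]
    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        quartets = gio.read_count_table(config.counts_path)
        _stage(log_lines, stage, t0)

        stage = "fit"
        t0 = time.perf_counter()
        fits = fit_table(quartets, config.library_sizes, config.zero_policy)
        artifacts["de_table"] = out / "de_table.tsv"
        gio.write_fits_table(fits, artifacts["de_table"])
        n_sig = count_significant(fits, config.alpha) if fits else 0
        log_lines.append(
            f"{len(fits)} contigs fitted; {n_sig} significant at "
            f"p < {config.alpha}"
        )
        _stage(log_lines, stage, t0)

        stage = "rank"
        t0 = time.perf_counter()
        if fits:
            ranked = rank_results(fits)
            top = select_top_k(ranked, config.top_k)
        else:
            ranked, top = [], []
        artifacts["ranked"] = out / "ranked.tsv"
        gio.write_ranked_table(ranked, artifacts["ranked"])
        artifacts["top_k"] = out / "top_k.tsv"
        gio.write_ranked_table(top, artifacts["top_k"])
        up = {r.fit.contig_id for r in top if r.direction == "up"}
        down = {r.fit.contig_id for r in top if r.direction == "down"}
        artifacts["up_ids"] = out / "up_ids.txt"
        artifacts["down_ids"] = out / "down_ids.txt"
        gio.write_id_set(up, artifacts["up_ids"])
        gio.write_id_set(down, artifacts["down_ids"])
        log_lines.append(
            f"top {len(top)}: {len(up)} up, {len(down)} down, "
            f"{len(top) - len(up) - len(down)} flat"
        )
        _stage(log_lines, stage, t0)

        if config.mapping_path is not None:
            stage = "enrich"
            t0 = time.perf_counter()
            mapping = gio.read_go_mapping(config.mapping_path)
            annotated = mapping.annotated_genes()
            for name, test_set in (("up", up), ("down", down)):
                key = f"enrichment_{name}"
                artifacts[key] = out / f"{key}.tsv"
                test_annot = test_set & annotated
                if test_annot:
                    results = enrich(
                        test_annot,
                        annotated - test_annot,
                        mapping,
                        config.fdr_cutoff,
                    )
                else:
                    results = []
                gio.write_enrichment_table(results, artifacts[key])
                log_lines.append(
                    f"{key}: {len(results)} terms at q < {config.fdr_cutoff}"
                )
            _stage(log_lines, stage, t0)
    except (GlmseqError, OSError) as exc:
        from .errors import InvalidInputError

        # Missing or unreadable files are input errors too.
        wrapper = (
            GlmseqError
            if isinstance(exc, GlmseqError)
            and not isinstance(exc, InvalidInputError)
            else InvalidInputError
        )
        raise wrapper(f"[stage {stage}] {exc}") from exc

    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    artifacts["log"] = log_path
    return artifacts
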
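"""emosub: person-centered subgrouping of emotion processing in conduct disorder.

Simulates case-control cohorts with trial-level neuropsychological task
data, reduces the 20 performance variables to three emotion-domain factor
scores (PCA + varimax + Anderson-Rubin), classifies individuals as
deficient/intact against age-bracketed normative cutoffs, and reproduces
the dimensional, categorical and correlate analyses of that design.
"""

__version__ = "0.1.0"

from . import (  # noqa: F401
    adjust,
    cohortgen,
    config,
    correlates,
    deficits,
    factors,
    pipeline,
    scales,
    stats,
    tasks,
)
from .cohortgen import Cohort, generate_cohort  # noqa: F401
from .config import (  # noqa: F401
    AnalysisOptions,
    ClinicalParams,
    CohortConfig,
    PipelineConfig,
    TaskParams,
    load_config,
)
from .pipeline import run_pipeline  # noqa: F401


def replication_config() -> "PipelineConfig":
    """The shipped fixture configuration (design constants of the study)."""
    from importlib.resources import files

    from .config import load_config as _load

    return _load(files("emosub.fixtures") / "replication.yaml")
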
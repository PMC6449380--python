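"""Exception types shared across the package."""


class NetpsychError(Exception):
    """Base class for all package-specific errors."""


class CalibrationInfeasibleError(NetpsychError):
    """Target marginal moments cannot be realised on the item's bounded support."""


class ConfigError(NetpsychError):
    """Invalid configuration (e.g. a non-positive-definite latent correlation)."""


class ValidationError(NetpsychError):
    """Input data violate the response-matrix contract (bounds, missingness, columns)."""


class RankDeficiencyError(NetpsychError):
    """Collinear parent set: the local regression design matrix is singular."""


class CyclicGraphError(NetpsychError):
    """An operation requiring an acyclic graph received a cyclic one."""


class UnresolvedDirectionError(NetpsychError):
    """A retained skeleton edge has an exactly tied orientation (probability 1/2)."""


class DegenerateFeatureError(NetpsychError):
    """A feature has zero variance across the cohort and cannot be z-scored."""


class UndefinedPathLengthError(NetpsychError):
    """No pair of nodes is connected: characteristic path length is undefined."""


class UndefinedCorrelationError(NetpsychError):
    """Correlation requested for a constant (zero-variance) vector."""


class ContractViolationError(NetpsychError):
    """A pipeline-stage contract was violated (e.g. VAQ nodes in the tested set)."""
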
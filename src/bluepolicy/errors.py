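"""Exception hierarchy.

Errors are split by which input is at fault so a command-line driver can
map them to distinct exit codes: data problems (the indicator CSV) versus
configuration problems (the rule YAML) versus construction problems
(an unsatisfiable synthetic-planting request).
"""


class BluePolicyError(Exception):
    """Base class for all package errors."""


class InputError(BluePolicyError):
    """A data input is absent, unreadable, or empty."""


class SchemaError(InputError):
    """The indicator table violates its structural contract (e.g. no
    iso3 column, duplicate country keys)."""


class DataError(InputError):
    """A cell value is unusable in a way stronger than 'missing'
    (e.g. an explicit NaN/inf passed where a number or None is required)."""


class HarmonizationError(InputError):
    """Country-name resolution would silently merge two rows."""


class ConfigurationError(BluePolicyError):
    """The rule configuration is malformed: undeclared condition ids,
    non-monotone connectives, bad cutoffs, inadmissible matrices."""


class ConstructionError(BluePolicyError):
    """A synthetic planting request cannot be satisfied by any value
    assignment under the given rules."""
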
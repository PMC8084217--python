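"""Exception hierarchy for survey-data loading and validation."""


class SurveyDataError(ValueError):
    """Base class for all survey-data problems."""


class SchemaError(SurveyDataError):
    """A required column is missing or a table cannot be parsed."""


class ValidationError(SurveyDataError):
    """A record violates a type invariant; message names the offending record."""


class VocabularyError(SurveyDataError):
    """A categorical field holds a value outside its controlled vocabulary."""


class ParameterError(SurveyDataError):
    """A design or profile parameter is out of its valid domain."""
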
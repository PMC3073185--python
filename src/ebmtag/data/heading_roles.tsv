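# Section-heading string (normalized: uppercase, no trailing colon,
# collapsed whitespace) -> rhetorical role {Aim, Method, Results, Conclusions}.
# Hand-audited mapping of common structured-abstract headings.
AIM	Aim
AIMS	Aim
AIM OF THE STUDY	Aim
OBJECTIVE	Aim
OBJECTIVES	Aim
PURPOSE	Aim
GOAL	Aim
GOALS	Aim
BACKGROUND	Aim
BACKGROUND AND PURPOSE	Aim
BACKGROUND AND AIMS	Aim
INTRODUCTION	Aim
CONTEXT	Aim
RATIONALE	Aim
HYPOTHESIS	Aim
STUDY OBJECTIVE	Aim
METHOD	Method
METHODS	Method
METHODOLOGY	Method
MATERIALS AND METHODS	Method
MATERIAL AND METHODS	Method
PATIENTS AND METHODS	Method
SUBJECTS AND METHODS	Method
METHODS AND MATERIALS	Method
DESIGN	Method
STUDY DESIGN	Method
DESIGN AND METHODS	Method
SETTING	Method
PATIENTS	Method
PARTICIPANTS	Method
SUBJECTS	Method
POPULATION	Method
SAMPLE	Method
INTERVENTION	Method
INTERVENTIONS	Method
PROCEDURE	Method
PROCEDURES	Method
MEASUREMENTS	Method
MAIN OUTCOME MEASURES	Method
OUTCOME MEASURES	Method
STATISTICAL ANALYSIS	Method
DATA COLLECTION	Method
RESULT	Results
RESULTS	Results
FINDINGS	Results
MAIN RESULTS	Results
MAIN FINDINGS	Results
OUTCOME	Results
OUTCOMES	Results
OBSERVATIONS	Results
CONCLUSION	Conclusions
CONCLUSIONS	Conclusions
CONCLUSIONS AND IMPLICATIONS	Conclusions
DISCUSSION	Conclusions
INTERPRETATION	Conclusions
SIGNIFICANCE	Conclusions
CLINICAL IMPLICATIONS	Conclusions
RELEVANCE	Conclusions
SUMMARY	Conclusions
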
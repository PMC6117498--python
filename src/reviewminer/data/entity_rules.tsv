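\d{1,2}(?:\.\d+)?°[CF]	#BODY_TEMPERATURE#
\d{1,3}(?:岁|-year-old|yo)	#AGE#
\d{3}(?:\.\d+)?cm	#HEIGHT#
\d{2,3}(?:\.\d+)?kg	#WEIGHT#
(?:[$¥€]\d+(?:\.\d+)?|\d+(?:\.\d+)?(?:元|yuan|dollars?))	#MONEY#
\d+(?:\.\d+)?%	#PERCENT#
(?:\d{4}-\d{1,2}-\d{1,2}|\d{1,2}/\d{1,2}/\d{2,4})	#DATE#
\d{1,2}:\d{2}(?::\d{2})?(?:am|pm)?	#TIME#
\d+(?:\.\d+)?	#NUMBER#
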
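>fam01 n_homeoboxes=1
DKDGRQTFTRYLTLEVEKEFHFNRYLTQKRYIEIAHAPCLSARQIKAHLQVRYMKWKEEP
>fam02 n_homeoboxes=1
DKRGRKTYTRNQTQELEKEVIPNRYFTRRQRIEIAMACCLQNRQIKIWFQRRSQKWCKEA
>fam03 n_homeoboxes=2
RKRGRQTVTRLQTLDLEQNHMANRYVWRVRCIEGAYALQLNERQIKIWFQNRMMKWKKVN
>fam04 n_homeoboxes=1
RKHKRQLYWAYRTLELEKEYHFVRDLTQRRRITIQCALCLTERPIKLWFQNRDMKWLKKN
>fam05 n_homeoboxes=1
IKEGRQTYWRYQQLELEEYFHFNFYHTDRRRFEIAHALCGEYRQMKIWFHNRRVNWKCEN
>fam06 n_homeoboxes=1
RKRGFQGYNRSQPLDLEKEFHKNRYLTEHRRIEIQHALCLTERNGKIWFWRSRMKYRSEN
>fam07 n_homeoboxes=1
RKDGRTTVTSYQTLRLEKEFHTNRYLSRRRQIWISHALCGTEQWIKIWFTNRVMKWMKWV
>fam08 n_homeoboxes=1
THAGRQISTHYQASELEAEVHFNRYLTRRRRNEINLALCLTERQIKIWWYFRFMKWEKEN
>fam09 n_homeoboxes=1
RKRGHVVSTRYQTHFDHKEFHFNCYLTRFRRIEEAHALMLTERKQKIAFQNRPMKWKRIN
>fam10 n_homeoboxes=1
RKRGRNTDTRYVRLELESEFHENHCLTGRRRIDDPHALCLTWEQMKIWCQNSRMKWKKVN
>fam11 n_homeoboxes=1
RTRSRQTYTRGQELEFEKEFHFNRYWTSRRRIEFNHALNLTSRCIKIVDQNRRLKWKVQG
>fam12 n_homeoboxes=1
RKAGFQHTTRYQTLELEKLFIFNSYLTRRRMIEKKWALCLTEIQNKRWCAYRTMKWKKEN
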
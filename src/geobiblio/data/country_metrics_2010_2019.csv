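country,n_articles,articles_per_million,total_citations_k,citations_per_year_median,citations_per_article_per_population_per_year,excess_articles,excess_pct
USA,5111,15.4,305.1,28.0,0.1,1174.5,23.0
UK,1691,25.1,85.6,24.4,0.4,410.5,24.3
Canada,560,14.6,30.6,28.4,0.7,43.8,7.8
France,386,5.7,24.1,33.7,0.5,-32.1,-8.3
Germany,376,4.5,21.3,36.0,0.4,1.3,0.3
Netherlands,374,21.3,17.7,25.9,1.5,55.6,14.9
Australia,339,13.2,20.4,28.9,1.1,-22.1,-6.5
China,225,0.2,15.9,39.6,0.0,-64.5,-28.7
Switzerland,216,24.8,10.2,29.9,3.4,20.4,9.4
Sweden,199,19.1,7.3,21.2,2.0,53.6,26.9
Denmark,182,31.1,6.6,21.2,3.6,48.5,26.6
Italy,133,2.3,6.7,35.3,0.6,-1.7,-1.3
Japan,112,0.9,6.0,26.9,0.2,-9.9,-8.8
Spain,97,2.0,8.9,39.6,0.8,-76.3,-78.7
Belgium,82,7.1,5.1,40.2,3.5,-24.1,-29.4
Norway,62,11.5,1.9,19.6,3.6,17.0,27.5
South Africa,58,1.0,2.4,25.5,0.4,4.3,7.3
New Zealand,53,10.3,2.2,27.8,5.4,1.8,3.4
Israel,47,5.0,2.0,22.0,2.3,-0.3,-0.5
Brazil,42,0.2,3.1,37.1,0.2,-26.1,-62.1
Finland,40,7.2,1.7,26.1,4.7,0.3,0.8
Austria,36,4.0,1.6,29.8,3.3,-1.9,-5.2
South Korea,34,0.7,1.7,39.1,0.8,-5.2,-15.3
India,34,0.0,1.3,21.3,0.0,2.8,8.4
Singapore,23,4.2,1.2,23.2,4.3,-5.9,-25.6
Ireland,17,3.4,0.7,29.5,5.9,-1.8,-10.7
Thailand,17,0.2,0.9,26.7,0.4,-6.9,-40.6
Kenya,17,0.3,0.5,23.7,0.4,4.5,26.7
Greece,14,1.3,0.7,31.9,3.0,-5.1,-36.2
Pakistan,13,0.1,0.4,11.6,0.1,2.4,18.5
Saudi Arabia,12,0.3,0.6,49.4,1.4,-4.9,-40.6
Bangladesh,11,0.1,0.2,14.6,0.1,6.0,54.3
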